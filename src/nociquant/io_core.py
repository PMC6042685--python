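"""Shared domain types, file I/O, configuration and logging.

All imaging pipelines consume :class:`ImageStack`, a labelled multi-channel
intensity array with 0-based ``(z, y, x)`` indexing (y increasing downward).
Temperature logs and behavior tables are thin validated wrappers around the
CSV formats the acquisition side produces.  Two TIFF dialects are accepted:
a single multi-channel file written by :func:`save_image_stack` (channel
labels carried in the image description as JSON), or one file per channel
bound together by a small YAML manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

log = logging.getLogger("nociquant")

#: Latency censoring cap in seconds: stimulation stops at 11 s, and animals
#: that have not responded carry this value with ``censored=True``.
LATENCY_CAP_S = 11.0


class FormatError(ValueError):
    """A file was readable but does not conform to the expected format."""


class ValidationError(ValueError):
    """In-memory data violates a domain invariant."""


# ---------------------------------------------------------------------------
# ImageStack
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """A 2D or 3D multi-channel intensity image.

    Parameters
    ----------
    channels
        Mapping of channel label (e.g. ``"GFP"``, ``"pMad"``, ``"CD2"``) to a
        non-negative intensity array indexed ``(z, y, x)`` or ``(y, x)``.
        Insertion order defines channel order.
    bit_depth
        8 or 16; intensities must lie in ``[0, 2**bit_depth - 1]``.
    pixel_size_um
        Microns per pixel, if known.
    """

    channels: dict[str, np.ndarray]
    bit_depth: int = 16
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("ImageStack needs at least one channel")
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        shapes = {name: np.asarray(a).shape for name, a in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValidationError(f"channel shapes differ: {shapes}")
        if len(first) not in (2, 3):
            raise ValidationError(f"pixel arrays must be 2D or 3D, got shape {first}")
        ceiling = 2 ** self.bit_depth - 1
        for name, a in self.channels.items():
            a = np.asarray(a)
            if a.size and (a.min() < 0 or a.max() > ceiling):
                raise ValidationError(
                    f"channel {name!r} intensities outside [0, {ceiling}]"
                )
            self.channels[name] = a

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def is_3d(self) -> bool:
        return len(self.shape) == 3

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]

    def dtype_for_depth(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)


def save_image_stack(path: str | Path, stack: ImageStack) -> Path:
    """Write a stack as one TIFF; channel labels go in the description JSON.

    The pixel payload is stored as ``(C, y, x)`` or ``(C, z, y, x)`` in the
    stack's native integer dtype, so a save/load round trip is bit exact.
    """
    path = Path(path)
    arr = np.stack([stack[name] for name in stack.channel_names])
    arr = arr.astype(stack.dtype_for_depth(), copy=False)
    meta = {
        "channels": stack.channel_names,
        "bit_depth": stack.bit_depth,
        "pixel_size_um": stack.pixel_size_um,
        "axes": "CZYX" if stack.is_3d else "CYX",
    }
    tifffile.imwrite(path, arr, description=json.dumps(meta))
    return path


def _stack_from_plain_tiff(arr: np.ndarray, path: Path) -> ImageStack:
    # No sidecar metadata: a 2D or 3D array is a single anonymous channel.
    if arr.ndim not in (2, 3):
        raise FormatError(f"{path}: cannot infer channels for shape {arr.shape}")
    bit_depth = 8 if arr.dtype.itemsize == 1 else 16
    return ImageStack({"ch0": arr}, bit_depth=bit_depth)


def load_image_stack(path: str | Path) -> ImageStack:
    """Load an :class:`ImageStack` from a TIFF file or a YAML channel manifest.

    A manifest binds per-channel TIFF files::

        channels:
          - {name: GFP, file: gfp.tif}
          - {name: pMad, file: pmad.tif}
        bit_depth: 16
        pixel_size_um: 0.1

    Relative manifest paths resolve against the manifest's directory.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        return _load_from_manifest(path)
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            desc = tif.pages[0].description
    # tifffile surfaces corrupt files as assorted exception types
    except (OSError, tifffile.TiffFileError, IndexError, ValueError) as exc:
        raise OSError(f"could not read TIFF {path}: {exc}") from exc
    meta = None
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = None
    if not isinstance(meta, dict) or "channels" not in meta:
        return _stack_from_plain_tiff(arr, path)
    names = list(meta["channels"])
    if arr.shape[0] != len(names):
        raise FormatError(
            f"{path}: {len(names)} channels declared but leading axis is {arr.shape[0]}"
        )
    return ImageStack(
        {name: arr[i] for i, name in enumerate(names)},
        bit_depth=int(meta.get("bit_depth", 16)),
        pixel_size_um=meta.get("pixel_size_um"),
    )


def _load_from_manifest(path: Path) -> ImageStack:
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "channels" not in manifest:
        raise FormatError(f"{path}: manifest must contain a 'channels' list")
    channels: dict[str, np.ndarray] = {}
    for entry in manifest["channels"]:
        name, file = entry["name"], entry["file"]
        fpath = Path(file)
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        try:
            channels[name] = tifffile.imread(fpath)
        except (OSError, tifffile.TiffFileError) as exc:
            raise OSError(f"could not read channel file {fpath}: {exc}") from exc
    shapes = {n: a.shape for n, a in channels.items()}
    if len(set(shapes.values())) > 1:
        raise FormatError(f"{path}: channel files disagree on shape: {shapes}")
    return ImageStack(
        channels,
        bit_depth=int(manifest.get("bit_depth", 16)),
        pixel_size_um=manifest.get("pixel_size_um"),
    )


# ---------------------------------------------------------------------------
# TemperatureLog
# ---------------------------------------------------------------------------

@dataclass
class TemperatureLog:
    """Thermocouple readings: strictly increasing times (s) and temps (°C)."""

    times: np.ndarray
    temps: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temps = np.asarray(self.temps, dtype=float)
        if self.times.shape != self.temps.shape or self.times.ndim != 1:
            raise ValidationError("times and temps must be 1D arrays of equal length")
        if len(self.times) < 2:
            raise FormatError("temperature log needs at least 2 samples")
        if not np.all(np.diff(self.times) > 0):
            raise FormatError("temperature log times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def load_temperature_log(path: str | Path) -> TemperatureLog:
    """Read a ``time_s,temp_C`` CSV; duplicate timestamps collapse to their mean."""
    df = pd.read_csv(path)
    for col in ("time_s", "temp_C"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    collapsed = df.groupby("time_s", sort=True)["temp_C"].mean().reset_index()
    if len(collapsed) < 2:
        raise FormatError(f"{path}: fewer than 2 distinct timestamps")
    return TemperatureLog(collapsed["time_s"].to_numpy(), collapsed["temp_C"].to_numpy())


def save_temperature_log(path: str | Path, tlog: TemperatureLog) -> Path:
    pd.DataFrame({"time_s": tlog.times, "temp_C": tlog.temps}).to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# BehaviorTable
# ---------------------------------------------------------------------------

@dataclass
class BehaviorTable:
    """Per-animal nocifensive behavior outcomes.

    Columns: ``animal_id``, ``genotype``, and at least one of ``latency_s``
    (seconds in (0, 11], NaN when not measured) and ``responded`` (nullable
    boolean).  ``censored`` marks latencies held at the 11 s cap; ``sex`` is
    optional.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        has_latency = "latency_s" in df.columns
        has_response = "responded" in df.columns
        if not has_latency and not has_response:
            raise FormatError("behavior table needs a latency_s or responded column")
        if "animal_id" not in df.columns:
            df["animal_id"] = np.arange(len(df))
        if "genotype" not in df.columns:
            raise FormatError("behavior table needs a genotype column")
        if has_latency:
            lat = pd.to_numeric(df["latency_s"], errors="coerce")
            bad = lat > LATENCY_CAP_S
            if bad.any():
                raise ValidationError(
                    f"latencies above the {LATENCY_CAP_S} s cap: "
                    f"{lat[bad].tolist()}"
                )
            if ((lat <= 0) & lat.notna()).any():
                raise ValidationError("latencies must be positive")
            df["latency_s"] = lat
            df["censored"] = lat == LATENCY_CAP_S
        if has_response:
            df["responded"] = df["responded"].astype("boolean")
        both_absent = pd.Series(True, index=df.index)
        if has_latency:
            both_absent &= df["latency_s"].isna()
        if has_response:
            both_absent &= df["responded"].isna()
        if both_absent.any():
            raise ValidationError(
                f"{int(both_absent.sum())} rows have neither latency nor response"
            )
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genotypes(self) -> list[str]:
        return list(pd.unique(self.data["genotype"]))


def load_behavior_table(path: str | Path) -> BehaviorTable:
    return BehaviorTable(pd.read_csv(path))


def save_behavior_table(path: str | Path, table: BehaviorTable) -> Path:
    table.data.to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Run-level parameters shared by the pipelines.

    ``bin_width_C`` is the temperature bin width (°C), ``baseline_frames``
    the number of initial frames averaged into F0, ``roi_diameter_px`` the
    calcium ROI disc diameter, ``corner_margin_px`` the gap between image
    corner and background ROI.
    """

    seed: int = 0
    bin_width_C: float = 1.0
    baseline_frames: int = 30
    roi_diameter_px: int = 6
    corner_margin_px: int = 2
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.bin_width_C <= 0:
            raise ValidationError("bin_width_C must be positive")
        if self.baseline_frames < 1:
            raise ValidationError("baseline_frames must be >= 1")
        if self.roi_diameter_px < 1:
            raise ValidationError("roi_diameter_px must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from YAML; keyword overrides (CLI flags) win over file keys."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def log_resolved(self) -> None:
        log.info("resolved config: %s", self)
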
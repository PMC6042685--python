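"""Synthetic raw data with known ground truth for every pipeline stage.

Each generator is a pure function of ``(truth, seed)`` and returns both the
simulated data and the truth object, so downstream recovery tests can compare
pipeline output against closed-form expectations.  The generators emulate:

* soma fields of view — a GFP-labelled nociceptor cell body whose nucleus is
  a GFP-negative hole, with programmable nuclear/cytoplasmic pMad levels, an
  additive background field, and Gaussian noise (clipped at zero, then
  quantized to the integer bit depth);
* sparse single-cell clone images — a GFP arbor inside a CD2-labelled
  neuropil ladder of known neuromere count, with bimodal intensities so Otsu
  thresholding separates foreground from background;
* GCaMP recordings — frame stacks on a jittered ~4 Hz camera clock plus a
  thermocouple log on its own, deliberately unsynchronized 4 Hz clock, with
  fluorescence following a programmable temperature-response curve during a
  slow heat ramp;
* behavior tables — right-skewed (lognormal by default) response latencies
  censored at the 11 s stimulation cap, and Bernoulli binary responses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .io_core import (
    LATENCY_CAP_S,
    BehaviorTable,
    ImageStack,
    TemperatureLog,
    ValidationError,
)

log = logging.getLogger("nociquant")

TRACT_LABELS = ["lat_L", "int_L", "med_L", "med_R", "int_R", "lat_R"]


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  semi_axes: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = center
    ay, ax = semi_axes
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _quantize(img: np.ndarray, bit_depth: int) -> tuple[np.ndarray, int, int]:
    """Clip to the representable range and round to integers.

    Returns the integer image plus counts of floor- and ceiling-clipped
    pixels.  A few floor clips are expected whenever Gaussian noise rides on
    a dim background; ceiling clips mean the programmed means saturate the
    bit depth and deserve a warning.
    """
    ceiling = 2 ** bit_depth - 1
    low = int(np.count_nonzero(img < 0))
    high = int(np.count_nonzero(img > ceiling))
    out = np.clip(np.rint(img), 0, ceiling)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return out.astype(dtype), low, high


# ---------------------------------------------------------------------------
# Soma images (nuclear pMad quantification)
# ---------------------------------------------------------------------------

@dataclass
class SomaTruth:
    """Ground truth for one soma field of view.

    ``nucleus_mask`` and ``cytoplasm_mask`` are disjoint; the pMad channel is
    ``true_nuclear_mean`` on the nucleus, ``true_cytoplasmic_mean`` on the
    cytoplasm, plus ``background_field`` everywhere and i.i.d. Gaussian noise
    of ``noise_sd``.  The GFP channel is ``gfp_mean`` on the cytoplasm only,
    leaving the nucleus as a GFP-negative hole.
    """

    nucleus_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    true_nuclear_mean: float
    true_cytoplasmic_mean: float
    background_field: np.ndarray
    noise_sd: float
    gfp_mean: float = 150.0
    bit_depth: int = 16
    clipped_pixels: int = 0

    def __post_init__(self) -> None:
        if np.logical_and(self.nucleus_mask, self.cytoplasm_mask).any():
            raise ValidationError("nucleus and cytoplasm masks must be disjoint")
        if self.true_nuclear_mean < 0 or self.true_cytoplasmic_mean < 0:
            raise ValidationError("true means must be non-negative")


def make_soma_truth(
    shape: tuple[int, int] = (128, 128),
    nuclear_mean: float = 100.0,
    cytoplasmic_mean: float = 40.0,
    background_offset: float = 20.0,
    background_gradient: tuple[float, float] = (0.05, 0.05),
    noise_sd: float = 5.0,
    gfp_mean: float = 150.0,
    bit_depth: int = 16,
) -> SomaTruth:
    """Default soma geometry: an elliptical cell body with an interior
    elliptical nucleus, both centered so the image corners stay pure
    background (the four-corner background estimator is then well-posed and
    a linear background gradient contributes zero net bias)."""
    h, w = shape
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    cell = _ellipse_mask(shape, center, (0.31 * h, 0.38 * w))
    nucleus = _ellipse_mask(shape, center, (0.09 * h, 0.12 * w))
    cytoplasm = cell & ~nucleus
    yy, xx = np.mgrid[0:h, 0:w]
    gy, gx = background_gradient
    background = (
        background_offset + gy * (yy - center[0]) + gx * (xx - center[1])
    )
    return SomaTruth(
        nucleus_mask=nucleus,
        cytoplasm_mask=cytoplasm,
        true_nuclear_mean=nuclear_mean,
        true_cytoplasmic_mean=cytoplasmic_mean,
        background_field=background,
        noise_sd=noise_sd,
        gfp_mean=gfp_mean,
        bit_depth=bit_depth,
    )


def generate_soma_image(truth: SomaTruth, seed: int) -> tuple[ImageStack, SomaTruth]:
    """Render one two-channel ("GFP", "pMad") soma image from truth."""
    rng = np.random.default_rng(seed)
    shape = truth.nucleus_mask.shape
    pmad = truth.background_field.astype(float).copy()
    pmad[truth.nucleus_mask] += truth.true_nuclear_mean
    pmad[truth.cytoplasm_mask] += truth.true_cytoplasmic_mean
    gfp = np.zeros(shape, dtype=float)
    gfp[truth.cytoplasm_mask] = truth.gfp_mean
    if truth.noise_sd > 0:
        pmad = pmad + rng.normal(0.0, truth.noise_sd, shape)
        gfp = gfp + rng.normal(0.0, truth.noise_sd, shape)
    pmad_q, lo_p, hi_p = _quantize(pmad, truth.bit_depth)
    gfp_q, lo_g, hi_g = _quantize(np.maximum(gfp, 0.0), truth.bit_depth)
    if hi_p or hi_g:
        log.warning(
            "soma image saturates the %d-bit ceiling on %d pixels",
            truth.bit_depth, hi_p + hi_g,
        )
    truth = replace(truth, clipped_pixels=lo_p + hi_p + lo_g + hi_g)
    stack = ImageStack({"GFP": gfp_q, "pMad": pmad_q}, bit_depth=truth.bit_depth)
    return stack, truth


# ---------------------------------------------------------------------------
# Clone images (axon-terminal morphometry)
# ---------------------------------------------------------------------------

@dataclass
class CloneTruth:
    """Ground truth for one flip-out clone image.

    ``clone_mask`` (GFP arbor) lies inside ``neuropil_mask`` (CD2 ladder of
    ``n_neuromeres`` equal segments).  ``branch_presence`` records the manual
    projection annotation: rows are neuromere offsets relative to
    ``entry_index``, columns are longitudinal tracts.
    """

    clone_mask: np.ndarray
    neuropil_mask: np.ndarray
    n_neuromeres: int
    entry_index: int
    branch_presence: pd.DataFrame
    gfp_fg: float = 180.0
    cd2_fg: float = 160.0
    background: float = 10.0
    noise_sd: float = 6.0
    bit_depth: int = 16
    low_contrast: bool = False

    def __post_init__(self) -> None:
        if self.n_neuromeres < 1:
            raise ValidationError("n_neuromeres must be >= 1")
        outside = self.clone_mask & ~self.neuropil_mask
        # allow a small margin: the arbor may spill a few pixels past the ladder
        if outside.sum() > 0.05 * max(self.clone_mask.sum(), 1):
            raise ValidationError("clone mask extends well outside the neuropil")

    @property
    def expected_normalized_area(self) -> float:
        """|clone| / (|neuropil| / n_neuromeres) — the closed-form result the
        morphometry pipeline should recover on a clean image."""
        return float(
            self.clone_mask.sum() / (self.neuropil_mask.sum() / self.n_neuromeres)
        )


def make_clone_truth(
    n_neuromeres: int = 10,
    neuromere_len_px: int = 24,
    neuropil_width_px: int = 56,
    margin_px: int = 20,
    entry_index: int = 4,
    clone_span: int = 3,
    branch_presence: pd.DataFrame | None = None,
    noise_sd: float = 6.0,
    gfp_fg: float = 180.0,
    cd2_fg: float = 160.0,
    bit_depth: int = 16,
) -> CloneTruth:
    """A neuropil "ladder" of ``n_neuromeres`` segments stacked along y, with
    an elliptical clone arbor entering at ``entry_index`` and spanning
    ``clone_span`` neuromeres."""
    h = n_neuromeres * neuromere_len_px + 2 * margin_px
    w = neuropil_width_px + 2 * margin_px
    neuropil = np.zeros((h, w), dtype=bool)
    neuropil[margin_px : h - margin_px, margin_px : w - margin_px] = True
    y0 = margin_px + entry_index * neuromere_len_px
    span_px = clone_span * neuromere_len_px
    center = (y0 + span_px / 2.0, (w - 1) / 2.0)
    clone = _ellipse_mask((h, w), center, (span_px / 2.0, neuropil_width_px / 2.4))
    clone &= neuropil
    if branch_presence is None:
        offsets = range(clone_span)
        branch_presence = pd.DataFrame(
            False, index=list(offsets), columns=TRACT_LABELS
        )
        branch_presence.loc[:, ["med_L", "med_R"]] = True
        branch_presence.loc[0, ["int_L", "int_R"]] = True
    return CloneTruth(
        clone_mask=clone,
        neuropil_mask=neuropil,
        n_neuromeres=n_neuromeres,
        entry_index=entry_index,
        branch_presence=branch_presence,
        gfp_fg=gfp_fg,
        cd2_fg=cd2_fg,
        noise_sd=noise_sd,
        bit_depth=bit_depth,
    )


def generate_clone_image(truth: CloneTruth, seed: int) -> tuple[ImageStack, CloneTruth]:
    """Render a two-channel ("GFP", "CD2") clone image with bimodal
    intensities; flags the truth when contrast falls below 4 noise SDs."""
    rng = np.random.default_rng(seed)
    shape = truth.clone_mask.shape
    gfp = np.full(shape, truth.background, dtype=float)
    gfp[truth.clone_mask] = truth.gfp_fg
    cd2 = np.full(shape, truth.background, dtype=float)
    cd2[truth.neuropil_mask] = truth.cd2_fg
    if truth.noise_sd > 0:
        gfp = gfp + rng.normal(0.0, truth.noise_sd, shape)
        cd2 = cd2 + rng.normal(0.0, truth.noise_sd, shape)
    contrast = min(truth.gfp_fg, truth.cd2_fg) - truth.background
    if truth.noise_sd > 0 and contrast < 4 * truth.noise_sd:
        log.warning("clone image contrast %.1f below separability floor", contrast)
        truth = replace(truth, low_contrast=True)
    gfp_q, _, _ = _quantize(gfp, truth.bit_depth)
    cd2_q, _, _ = _quantize(cd2, truth.bit_depth)
    stack = ImageStack({"GFP": gfp_q, "CD2": cd2_q}, bit_depth=truth.bit_depth)
    return stack, truth


# ---------------------------------------------------------------------------
# GCaMP recordings (calcium imaging)
# ---------------------------------------------------------------------------

@dataclass
class GaussianResponse:
    """Temperature-response curve: ΔF/F0 fraction as a Gaussian bump.

    The default emulates a control thermal response whose binned maximum
    falls in the 43 °C bin: under ``[k, k+1)`` binning a curve reported as
    "peaking at 43 °C" has its true peak somewhere in ``[43, 44)``, so the
    generative peak sits at the bin midpoint 43.5 (a peak exactly on the
    bin edge would make the two adjacent bins tie in expectation and leave
    the binned maximum to noise).
    """

    center_C: float = 43.5
    width_C: float = 2.0
    amplitude: float = 0.5

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")

    def __call__(self, temp_C: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(temp_C, dtype=float)
        out = self.amplitude * np.exp(-((t - self.center_C) ** 2) / (2 * self.width_C**2))
        return out if out.ndim else float(out)


@dataclass
class RaisedCosineResponse:
    """A response bump with strictly compact support.

    ΔF/F0 fraction is ``amplitude/2 * (1 + cos(pi*(T - center)/half_width))``
    for ``|T - center| <= half_width`` and exactly zero outside.  Useful for
    simulation studies that need two cohorts whose programmed responses are
    *identical* outside a known temperature range, so any group difference
    detected there is a false positive by construction.
    """

    center_C: float = 43.5
    half_width_C: float = 7.0
    amplitude: float = 1.5

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")

    def __call__(self, temp_C: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(temp_C, dtype=float)
        u = np.clip(np.abs(t - self.center_C) / self.half_width_C, 0.0, 1.0)
        out = self.amplitude / 2.0 * (1.0 + np.cos(np.pi * u)) * (u < 1.0)
        return out if out.ndim else float(out)


@dataclass
class SumResponse:
    """Pointwise sum of response curves (e.g. control profile + extra bump)."""

    parts: tuple

    def __call__(self, temp_C):
        t = np.asarray(temp_C, dtype=float)
        out = sum(np.asarray(p(t), dtype=float) for p in self.parts)
        return out if np.ndim(out) else float(out)


@dataclass
class RecordingTruth:
    """Ground truth for one GCaMP recording.

    Fluorescence at the terminal is ``f0_true * (1 + response_curve(T))``
    where ``T`` is the probe temperature; the probe ramps from ``ambient_C``
    at ``ramp_rate`` °C/s starting at ``ramp_start_s``, capped at ``max_C``.
    The thermocouple samples on its own 4 Hz clock shifted by
    ``clock_offset_s`` relative to the camera clock.
    """

    response_curve: Callable[[float], float] = field(default_factory=GaussianResponse)
    ramp_rate: float = 0.1
    f0_true: float = 100.0
    frame_rate: float = 4.0
    clock_offset_s: float = 0.25
    ambient_C: float = 25.0
    ramp_start_s: float = 10.0
    max_C: float = 50.0
    noise_sd: float = 5.0
    frame_shape: tuple[int, int, int] = (10, 24, 32)
    background: float = 10.0
    signal_radius_px: float = 5.0
    time_jitter_sd: float = 0.01
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.ramp_rate <= 0:
            raise ValidationError("ramp_rate must be positive")

    def temperature_at(self, t: np.ndarray | float) -> np.ndarray:
        """Probe temperature on the camera clock."""
        t = np.asarray(t, dtype=float)
        ramp = self.ambient_C + self.ramp_rate * np.maximum(t - self.ramp_start_s, 0.0)
        return np.minimum(ramp, self.max_C)


@dataclass
class CalciumRecording:
    """Frame-indexed fluorescence stacks plus an independent temperature log.

    ``frames`` is a ``(t, z, y, x)`` array (one optical channel); the
    temperature log lives on the thermocouple's own clock.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    log: TemperatureLog
    roi_center: tuple[float, float]
    roi_diameter_px: int = 6
    animal_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 4:
            raise ValidationError("frames must be a (t, z, y, x) array")
        if len(self.frame_times) != self.frames.shape[0]:
            raise ValidationError("one timestamp per frame required")
        if not np.all(np.diff(self.frame_times) > 0):
            raise ValidationError("frame times must be increasing")


def generate_gcamp_recording(
    truth: RecordingTruth, duration_s: float, seed: int
) -> tuple[CalciumRecording, RecordingTruth]:
    """Simulate a recording of ``duration_s`` seconds.

    The terminal is a bright disc whose intensity follows the programmed
    response curve; elsewhere the frame is flat background.  Camera frame
    times carry small Gaussian jitter; the thermocouple log is sampled at
    4 Hz on a clock shifted by ``clock_offset_s``.
    """
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(math.floor(duration_s * truth.frame_rate))
    base_times = np.arange(n_frames) / truth.frame_rate
    if truth.time_jitter_sd > 0:
        jitter = rng.normal(0.0, truth.time_jitter_sd, n_frames)
        frame_times = np.maximum.accumulate(base_times + jitter)
        frame_times += np.arange(n_frames) * 1e-9  # enforce strict increase
    else:
        frame_times = base_times

    # thermocouple: recorded timestamps on its own clock; the reading at
    # recorded time tau is the true probe temperature at camera time
    # tau + clock_offset_s
    log_times = np.arange(0.0, duration_s, 0.25)
    log_temps = truth.temperature_at(log_times + truth.clock_offset_s)
    tlog = TemperatureLog(log_times, log_temps)

    temp_at_frames = truth.temperature_at(frame_times)
    signal = truth.f0_true * (1.0 + np.asarray(truth.response_curve(temp_at_frames)))

    nz, ny, nx = truth.frame_shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= truth.signal_radius_px**2
    frames_f = np.full((n_frames, nz, ny, nx), truth.background, dtype=np.float32)
    frames_f[:, :, disc] = signal[:, None, None].astype(np.float32)
    if truth.noise_sd > 0:
        frames_f += rng.normal(0.0, truth.noise_sd, frames_f.shape).astype(np.float32)
    frames, _, _ = _quantize(frames_f, truth.bit_depth)

    rec = CalciumRecording(
        frames=frames,
        frame_times=frame_times,
        log=tlog,
        roi_center=(cy, cx),
        roi_diameter_px=6,
    )
    return rec, truth


def ramp_duration_s(truth: RecordingTruth) -> float:
    """Seconds from recording start until the probe reaches ``max_C``."""
    return truth.ramp_start_s + (truth.max_C - truth.ambient_C) / truth.ramp_rate


# ---------------------------------------------------------------------------
# Behavior tables
# ---------------------------------------------------------------------------

@dataclass
class BehaviorTruth:
    """Per-genotype generative model for behavior outcomes.

    ``latency_lognormal`` maps genotype to ``(mu, sigma)`` of the underlying
    lognormal (right-skewed, positive); draws above the 11 s cap are recorded
    as 11 with the censored flag set.  ``response_prob`` maps genotype to a
    Bernoulli response probability.  Each genotype needs at least one of the
    two.  ``n`` gives per-genotype sample sizes.
    """

    n: Mapping[str, int]
    latency_lognormal: Mapping[str, tuple[float, float]] | None = None
    response_prob: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latency_lognormal is None and self.response_prob is None:
            raise ValidationError("need a latency model and/or response probabilities")
        for g, count in self.n.items():
            if count < 1:
                raise ValidationError(f"n must be >= 1 for genotype {g!r}")
        if self.response_prob:
            for g, p in self.response_prob.items():
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(f"response_prob out of [0,1] for {g!r}")


def generate_behavior_dataset(truth: BehaviorTruth) -> BehaviorTable:
    """Draw a per-animal behavior table; deterministic given ``truth.seed``."""
    rng = np.random.default_rng(truth.seed)
    rows = []
    for genotype, count in truth.n.items():
        lat = None
        if truth.latency_lognormal and genotype in truth.latency_lognormal:
            mu, sigma = truth.latency_lognormal[genotype]
            lat = rng.lognormal(mu, sigma, count)
            lat = np.minimum(lat, LATENCY_CAP_S)
        resp = None
        if truth.response_prob and genotype in truth.response_prob:
            resp = rng.random(count) < truth.response_prob[genotype]
        for i in range(count):
            rows.append(
                {
                    "animal_id": f"{genotype}_{i:04d}",
                    "genotype": genotype,
                    "latency_s": float(lat[i]) if lat is not None else np.nan,
                    "responded": bool(resp[i]) if resp is not None else pd.NA,
                }
            )
    df = pd.DataFrame(rows)
    if truth.latency_lognormal is None:
        df = df.drop(columns=["latency_s"])
    if truth.response_prob is None:
        df = df.drop(columns=["responded"])
    return BehaviorTable(df)
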
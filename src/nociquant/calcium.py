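"""GCaMP ΔF/F0 analysis against an asynchronous thermal-ramp stimulus.

Each recording is a time series of small Z-stacks (~4 Hz) of the nociceptor
axon terminals plus a thermocouple log on its own clock.  Per frame, the
Z-stack is max-projected and the mean intensity of a 6-pixel-diameter disc
ROI (centered on the A6 neuromere centroid) gives F.  The baseline F0 is the
mean of the first 30 frames, ΔF/F0 = 100·(F−F0)/F0.  Because camera and
thermocouple are not synchronized, the probe temperature at each frame time
is linearly interpolated from the log (endpoint hold outside its span).
Responses are compared across animals after averaging ΔF/F0 within 1 °C
temperature bins anchored at integer °C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import TemperatureLog, ValidationError
from .synthetic import CalciumRecording

log = logging.getLogger("nociquant")


@dataclass
class DffTrace:
    """Per-frame fluorescence, baseline, percent change, and probe temperature."""

    f: np.ndarray
    f0: float
    dff: np.ndarray  # percent
    temp_at_frame: np.ndarray


@dataclass
class BinnedResponse:
    """ΔF/F0 averaged within integer-anchored temperature bins.

    ``bin_left`` holds the lower edge of each occupied bin ``[k, k+1)``;
    empty bins are simply absent (missing, never zero).
    """

    bin_left: np.ndarray
    mean_dff: np.ndarray
    n_frames: np.ndarray
    animal_id: str = ""
    group: str = ""

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_left + 0.5

    def as_series(self) -> pd.Series:
        return pd.Series(self.mean_dff, index=self.bin_left)


def _roi_mask(shape: tuple[int, int], center: tuple[float, float],
              diameter_px: int) -> np.ndarray:
    # pixel centers strictly within diameter/2 of the ROI center
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    r = diameter_px / 2.0
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 < r**2


def roi_trace(recording: CalciumRecording) -> np.ndarray:
    """Per-frame mean intensity over the disc ROI of the max projection."""
    cy, cx = recording.roi_center
    r = recording.roi_diameter_px / 2.0
    _, _, ny, nx = recording.frames.shape
    if cy - r < -0.5 or cx - r < -0.5 or cy + r > ny - 0.5 or cx + r > nx - 0.5:
        raise ValidationError("ROI disc extends beyond the frame")
    mask = _roi_mask((ny, nx), (cy, cx), recording.roi_diameter_px)
    if not mask.any():
        raise ValidationError("ROI contains no pixel centers")
    proj = recording.frames.max(axis=1)  # (t, y, x)
    return proj[:, mask].mean(axis=1)


def dff(f: np.ndarray, n_baseline: int = 30) -> tuple[float, np.ndarray]:
    """Baseline F0 (mean of the first ``n_baseline`` frames) and percent
    change per frame."""
    f = np.asarray(f, dtype=float)
    if len(f) < n_baseline:
        raise ValidationError(
            f"need at least {n_baseline} frames for the baseline, got {len(f)}"
        )
    f0 = float(f[:n_baseline].mean())
    if f0 <= 0:
        raise ValidationError(f"baseline F0 must be positive, got {f0}")
    return f0, 100.0 * (f - f0) / f0


def interpolate_temperature(
    tlog: TemperatureLog, frame_times: np.ndarray
) -> np.ndarray:
    """Probe temperature at each frame time, linearly interpolated between
    log samples; times outside the log's span hold the end temperatures."""
    return np.interp(np.asarray(frame_times, dtype=float), tlog.times, tlog.temps)


def bin_by_temperature(
    dff_values: np.ndarray,
    temps: np.ndarray,
    bin_width: float = 1.0,
    animal_id: str = "",
    group: str = "",
) -> BinnedResponse:
    """Average ΔF/F0 within ``[k·w, (k+1)·w)`` °C bins anchored at integer
    multiples of the width; only occupied bins are reported."""
    dff_values = np.asarray(dff_values, dtype=float)
    temps = np.asarray(temps, dtype=float)
    if dff_values.shape != temps.shape:
        raise ValidationError("dff and temperature arrays must align")
    idx = np.floor(temps / bin_width).astype(int)
    order = np.argsort(idx, kind="stable")
    uniq, starts, counts = np.unique(idx[order], return_index=True, return_counts=True)
    sums = np.add.reduceat(dff_values[order], starts)
    return BinnedResponse(
        bin_left=uniq * bin_width,
        mean_dff=sums / counts,
        n_frames=counts,
        animal_id=animal_id,
        group=group,
    )


def analyze_recording(
    recording: CalciumRecording,
    n_baseline: int = 30,
    bin_width: float = 1.0,
) -> tuple[DffTrace, BinnedResponse]:
    """Full per-animal pipeline: ROI trace → ΔF/F0 → temperature → binning."""
    f = roi_trace(recording)
    f0, d = dff(f, n_baseline)
    temps = interpolate_temperature(recording.log, recording.frame_times)
    trace = DffTrace(f=f, f0=f0, dff=d, temp_at_frame=temps)
    binned = bin_by_temperature(
        d, temps, bin_width,
        animal_id=recording.animal_id, group=recording.group,
    )
    return trace, binned


def group_mean_curve(responses: list[BinnedResponse]) -> pd.DataFrame:
    """Mean ± SE of per-animal binned ΔF/F0; bins an animal lacks are
    excluded for that animal."""
    wide = pd.DataFrame({i: r.as_series() for i, r in enumerate(responses)})
    n = wide.notna().sum(axis=1)
    mean = wide.mean(axis=1)
    se = wide.std(axis=1, ddof=1) / np.sqrt(n)
    out = pd.DataFrame({"bin_left": wide.index, "mean_dff": mean,
                        "se_dff": se, "n_animals": n})
    return out.reset_index(drop=True)


def compare_binned_groups(
    group_a: list[BinnedResponse],
    group_b: list[BinnedResponse],
    min_n: int = 2,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per temperature bin on per-animal mean ΔF/F0.

    Bins with fewer than ``min_n`` animals in either group are flagged
    ``testable=False`` and carry no p-value.
    """
    from .stats import mann_whitney_u  # behavior_stats owns the test

    wide_a = pd.DataFrame({i: r.as_series() for i, r in enumerate(group_a)})
    wide_b = pd.DataFrame({i: r.as_series() for i, r in enumerate(group_b)})
    bins = sorted(set(wide_a.index) | set(wide_b.index))
    rows = []
    for b in bins:
        xa = wide_a.loc[b].dropna().to_numpy() if b in wide_a.index else np.array([])
        xb = wide_b.loc[b].dropna().to_numpy() if b in wide_b.index else np.array([])
        testable = len(xa) >= min_n and len(xb) >= min_n
        if testable:
            res = mann_whitney_u(xa, xb)
            stat, p = res.statistic, res.p_value
        else:
            stat, p = np.nan, np.nan
        rows.append(
            {"bin_left": b, "n_a": len(xa), "n_b": len(xb),
             "testable": testable, "U": stat, "p_value": p}
        )
    return pd.DataFrame(rows)


def plot_group_curves(curves: dict[str, pd.DataFrame], path=None):
    """Mean ± SE binned ΔF/F0 curves, one line per group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, df in curves.items():
        centers = df["bin_left"] + 0.5
        ax.errorbar(centers, df["mean_dff"], yerr=df["se_dff"],
                    label=name, capsize=2)
    ax.set_xlabel("probe temperature (°C)")
    ax.set_ylabel("ΔF/F0 (%)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
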
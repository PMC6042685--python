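"""Axon-terminal morphometry for sparse single-cell clones.

Terminal arbor size is the count of GFP-positive pixels after Otsu
binarization, normalized to the average size of one neuromere (CD2-positive
pixels divided by the neuromere count in the cropped image) to compensate for
ventral-nerve-cord size differences.  Projection patterns are manual
presence/absence annotations per (neuromere, longitudinal tract); clones
entering at different segments are aligned on their entry neuromere before
computing per-position projection percentages for heat maps.

Otsu thresholding here is the classic histogram formulation: the threshold
maximizes between-class variance over a 256-bin histogram of the channel's
intensity range (16-bit data is effectively rescaled by the binning), ties
broken toward the smallest threshold, foreground strictly greater than the
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import FormatError, ImageStack, ValidationError

log = logging.getLogger("nociquant")


class NotBinarizableError(ValueError):
    """The channel has no intensity structure Otsu can split (exclusion rule)."""


@dataclass
class TerminalAreaResult:
    """Per-clone terminal area, normalized to mean neuromere size.

    ``normalized_area = gfp_pixels / (cd2_pixels / n_neuromeres)``.
    ``excluded`` marks clones whose signal could not be binarized; their
    reason is recorded and their area should not enter group statistics.
    """

    gfp_pixels: int
    cd2_pixels: int
    n_neuromeres: int
    normalized_area: float
    gfp_threshold: float
    cd2_threshold: float
    excluded: bool = False
    exclusion_reason: str = ""
    clone_id: str = ""
    enhancement_gain: float = 1.0


@dataclass
class ProjectionProfile:
    """Manual annotation of one clone's terminal branches.

    ``presence`` is a boolean DataFrame indexed by absolute neuromere index
    with one column per longitudinal tract; ``entry_index`` is the neuromere
    where the clone's axon enters the CNS (alignment origin).
    """

    entry_index: int
    presence: pd.DataFrame
    clone_id: str = ""

    def __post_init__(self) -> None:
        if self.entry_index not in self.presence.index:
            raise ValidationError("entry neuromere missing from presence table")
        if not self.presence.loc[self.entry_index].any():
            raise ValidationError("profile must be present at its entry neuromere")


@dataclass
class HeatMap:
    """Percent of clones projecting to each (relative neuromere, tract)."""

    percent: pd.DataFrame  # index: neuromere offset, columns: tracts
    n_clones: int


# ---------------------------------------------------------------------------
# Otsu thresholding
# ---------------------------------------------------------------------------

def _between_class_variance(counts: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """sigma_b^2(k) for splitting after bin k (background <= k < foreground)."""
    counts = counts.astype(float)
    total = counts.sum()
    w0 = np.cumsum(counts)
    w1 = total - w0
    mass = np.cumsum(counts * centers)
    mu0 = np.divide(mass, w0, out=np.zeros_like(mass), where=w0 > 0)
    mu1 = np.divide(mass[-1] - mass, w1, out=np.zeros_like(mass), where=w1 > 0)
    return w0 * w1 * (mu0 - mu1) ** 2


def otsu_threshold(channel: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold over the channel's intensity histogram.

    Integer data whose range spans fewer than ``nbins`` levels is
    histogrammed at exact integer levels; anything else uses ``nbins`` equal
    bins over ``[min, max]``.  Returns the threshold ``t``; foreground is
    ``channel > t``.  Ties in between-class variance resolve to the smallest
    threshold.
    """
    vals = np.asarray(channel).ravel()
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        raise NotBinarizableError("constant channel cannot be binarized")
    integral = np.issubdtype(vals.dtype, np.integer)
    if integral and hi - lo < nbins:
        levels = np.arange(int(lo), int(hi) + 1)
        counts = np.bincount((vals - int(lo)).astype(np.int64),
                             minlength=len(levels))
        centers = levels.astype(float)
        thresholds = centers  # foreground strictly greater than level k
    else:
        counts, edges = np.histogram(vals, bins=nbins, range=(lo, hi))
        centers = (edges[:-1] + edges[1:]) / 2.0
        thresholds = edges[1:]
    sigma_b = _between_class_variance(counts, centers)
    k = int(np.argmax(sigma_b[:-1]))  # last split leaves empty foreground
    return float(thresholds[k])


# ---------------------------------------------------------------------------
# Linear enhancement
# ---------------------------------------------------------------------------

def upper_decile_mean(channel: np.ndarray) -> float:
    """Mean of the brightest 10% of pixels — the matching statistic used for
    linear enhancement of dim clones."""
    vals = np.sort(np.asarray(channel, dtype=float).ravel())
    k = max(1, int(round(0.1 * vals.size)))
    return float(vals[-k:].mean())


def match_enhance(
    channel: np.ndarray, reference_upper_decile_mean: float
) -> tuple[np.ndarray, float]:
    """Scale a dim channel by gain ``g`` (offset 0) so its upper-decile mean
    matches the reference's; the map is monotone so relative brightness order
    is preserved.  Returns ``(scaled channel, g)``."""
    src = upper_decile_mean(channel)
    if src <= 0:
        raise NotBinarizableError("zero-intensity channel cannot be enhanced")
    g = reference_upper_decile_mean / src
    return np.asarray(channel, dtype=float) * g, float(g)


# ---------------------------------------------------------------------------
# Terminal area
# ---------------------------------------------------------------------------

def terminal_area(
    clone: ImageStack,
    n_neuromeres: int,
    clone_id: str = "",
    enhance_reference: float | None = None,
    crop: tuple[int, int, int, int] | None = None,
) -> TerminalAreaResult:
    """Binarize GFP and CD2 independently and compute normalized terminal area.

    ``crop`` is an optional ``(y0, x0, y1, x1)`` box excluding other clones
    in the field.  When ``enhance_reference`` (a control image's upper-decile
    mean) is given, both channels are linearly enhanced before binarization.
    Clones whose channels cannot be binarized are returned with
    ``excluded=True`` rather than raising, implementing the exclusion rule
    for signal too dim for Otsu.
    """
    from .pmad import max_project  # local import: pmad also uses this module

    for required in ("GFP", "CD2"):
        if required not in clone.channel_names:
            raise FormatError(f"clone image lacks required channel {required!r}")
    if n_neuromeres < 1:
        raise ValidationError("n_neuromeres must be >= 1")
    proj = max_project(clone)
    gfp = np.asarray(proj["GFP"], dtype=float)
    cd2 = np.asarray(proj["CD2"], dtype=float)
    if crop is not None:
        y0, x0, y1, x1 = crop
        gfp, cd2 = gfp[y0:y1, x0:x1], cd2[y0:y1, x0:x1]
    gain = 1.0
    try:
        if enhance_reference is not None:
            gfp, gain = match_enhance(gfp, enhance_reference)
            cd2, _ = match_enhance(cd2, enhance_reference)
        t_gfp = otsu_threshold(gfp)
        t_cd2 = otsu_threshold(cd2)
    except NotBinarizableError as exc:
        log.warning("clone %s excluded: %s", clone_id or "<unnamed>", exc)
        return TerminalAreaResult(
            gfp_pixels=0, cd2_pixels=0, n_neuromeres=n_neuromeres,
            normalized_area=float("nan"), gfp_threshold=float("nan"),
            cd2_threshold=float("nan"), excluded=True,
            exclusion_reason=str(exc), clone_id=clone_id,
        )
    gfp_px = int((gfp > t_gfp).sum())
    cd2_px = int((cd2 > t_cd2).sum())
    if cd2_px == 0:
        return TerminalAreaResult(
            gfp_pixels=gfp_px, cd2_pixels=0, n_neuromeres=n_neuromeres,
            normalized_area=float("nan"), gfp_threshold=t_gfp,
            cd2_threshold=t_cd2, excluded=True,
            exclusion_reason="no CD2-positive pixels", clone_id=clone_id,
        )
    return TerminalAreaResult(
        gfp_pixels=gfp_px,
        cd2_pixels=cd2_px,
        n_neuromeres=n_neuromeres,
        normalized_area=gfp_px / (cd2_px / n_neuromeres),
        gfp_threshold=t_gfp,
        cd2_threshold=t_cd2,
        clone_id=clone_id,
        enhancement_gain=gain,
    )


# ---------------------------------------------------------------------------
# Projection alignment and heat maps
# ---------------------------------------------------------------------------

def align_profiles(
    profiles: Sequence[ProjectionProfile],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Re-index each profile by offset from its entry neuromere.

    Returns ``(presence, offsets, tracts)`` where ``presence`` is a boolean
    array of shape ``(n_clones, n_offsets, n_tracts)``, padded with absent at
    offsets a clone's annotation does not cover.
    """
    if not profiles:
        raise ValidationError("align_profiles needs at least one profile")
    tracts: list[str] = []
    for p in profiles:
        for c in p.presence.columns:
            if c not in tracts:
                tracts.append(c)
    offset_sets = [
        np.asarray(p.presence.index) - p.entry_index for p in profiles
    ]
    lo = min(int(o.min()) for o in offset_sets)
    hi = max(int(o.max()) for o in offset_sets)
    offsets = np.arange(lo, hi + 1)
    presence = np.zeros((len(profiles), len(offsets), len(tracts)), dtype=bool)
    for i, (p, offs) in enumerate(zip(profiles, offset_sets)):
        for row_idx, off in zip(p.presence.index, offs):
            j = int(off) - lo
            for k, tract in enumerate(tracts):
                if tract in p.presence.columns:
                    presence[i, j, k] = bool(p.presence.loc[row_idx, tract])
    return presence, offsets, tracts


def projection_heatmap(
    presence: np.ndarray, offsets: np.ndarray, tracts: Sequence[str]
) -> HeatMap:
    """Percent of clones present at each aligned (offset, tract) position."""
    n_clones = presence.shape[0]
    if n_clones < 1:
        raise ValidationError("heat map needs at least one clone")
    percent = 100.0 * presence.sum(axis=0) / n_clones
    return HeatMap(
        percent=pd.DataFrame(percent, index=offsets, columns=list(tracts)),
        n_clones=n_clones,
    )


def plot_heatmap(heatmap: HeatMap, path=None):
    """Render the projection heat map (percent per offset and tract)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(
        heatmap.percent.to_numpy(), cmap="magma", vmin=0, vmax=100,
        aspect="auto",
    )
    ax.set_xticks(range(len(heatmap.percent.columns)))
    ax.set_xticklabels(heatmap.percent.columns, rotation=45)
    ax.set_yticks(range(len(heatmap.percent.index)))
    ax.set_yticklabels(heatmap.percent.index)
    ax.set_ylabel("neuromere offset from entry")
    fig.colorbar(im, ax=ax, label=f"% of clones (n={heatmap.n_clones})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
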
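"""Nuclear pMad immunofluorescence quantification.

The readout of BMP pathway activity is the mean phospho-Mad immunosignal in
the nociceptor nucleus, measured on a maximum-intensity projection.  The
nucleus appears as a GFP-negative hole inside the GFP-filled cell body; its
ROI can be segmented automatically or supplied as a manual mask.  Local
background is estimated by translating the nucleus ROI into the four image
corners and averaging, and subtracted from the raw nuclear mean.  Corrected
values are reported as percent change relative to control specimens processed
in the same staining batch, since absolute immunofluorescence is not
comparable across staining solutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.measure import label, regionprops

from .io_core import ImageStack, ValidationError
from .morphometry import otsu_threshold

log = logging.getLogger("nociquant")


class SegmentationError(RuntimeError):
    """Automatic nucleus segmentation failed; supply a manual mask."""


class GeometryError(ValueError):
    """An ROI does not fit the image geometry it is applied to."""


@dataclass
class NucleusROI:
    """A delineated nucleus: boolean mask, centroid (y, x), and pixel area."""

    mask: np.ndarray
    centroid: tuple[float, float]
    area_px: int

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "NucleusROI":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValidationError("nucleus mask is empty")
        ys, xs = np.nonzero(mask)
        return cls(mask=mask, centroid=(float(ys.mean()), float(xs.mean())),
                   area_px=int(mask.sum()))


@dataclass
class PMadMeasurement:
    """Per-neuron nuclear pMad readout.

    ``corrected = raw_nuclear_mean - background_mean`` and may legitimately
    be negative (recorded as-is); negatives simply mean the nucleus was
    dimmer than the corner background estimate.
    """

    raw_nuclear_mean: float
    background_mean: float
    corrected: float
    specimen_id: str = ""
    batch_id: str = ""
    animal_id: str = ""
    cytoplasm_mean: float | None = None


@dataclass
class NormalizedPMad:
    """Group effect relative to co-processed controls, in percent."""

    percent_change: float
    n_control: int
    n_experimental: int
    batch_id: str = ""


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def max_project(stack: ImageStack) -> ImageStack:
    """Maximum-intensity projection along z; a 2D stack passes through."""
    if not stack.is_3d:
        return stack
    if stack.shape[0] == 0:
        raise ValidationError("empty z-stack")
    return ImageStack(
        {name: stack[name].max(axis=0) for name in stack.channel_names},
        bit_depth=stack.bit_depth,
        pixel_size_um=stack.pixel_size_um,
    )


def segment_nucleus(
    gfp_projection: np.ndarray,
    seed_point: tuple[int, int] | None = None,
    mask: np.ndarray | None = None,
) -> NucleusROI:
    """Find the nucleus as the GFP-negative hole enclosed by cytoplasmic GFP.

    The GFP projection is Otsu-thresholded; among below-threshold connected
    components that do not touch the image border (i.e. holes fully enclosed
    by GFP-positive cytoplasm), the largest is returned — or the one
    containing ``seed_point`` when given.  In manual-ROI mode (``mask``
    supplied) the mask is validated and returned verbatim.
    """
    if mask is not None:
        return NucleusROI.from_mask(mask)
    gfp = np.asarray(gfp_projection)
    if gfp.ndim != 2:
        raise ValidationError("segment_nucleus expects a 2D projection")
    if np.ptp(gfp) == 0:
        raise SegmentationError(
            "uniform GFP image: no enclosed hole; supply a manual mask"
        )
    t = otsu_threshold(gfp)
    background = gfp <= t
    labels = label(background, connectivity=1)
    border = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    enclosed = [
        p for p in regionprops(labels)
        if p.label not in border
    ]
    if not enclosed:
        raise SegmentationError(
            "no GFP-negative hole enclosed by cytoplasm; supply a manual mask"
        )
    if seed_point is not None:
        lbl = labels[seed_point]
        picked = next((p for p in enclosed if p.label == lbl), None)
        if picked is None:
            raise SegmentationError("seed point is not inside an enclosed hole")
    else:
        picked = max(enclosed, key=lambda p: p.area)
    return NucleusROI.from_mask(labels == picked.label)


def _corner_offsets(
    shape: tuple[int, int], bbox: tuple[int, int, int, int], margin_px: int
) -> list[tuple[int, int]]:
    h_img, w_img = shape
    y0, x0, y1, x1 = bbox
    h, w = y1 - y0, x1 - x0
    if h > h_img // 2 or w > w_img // 2:
        raise GeometryError(
            f"ROI bounding box {h}x{w} exceeds half the image {h_img}x{w_img}"
        )
    lo_y, hi_y = margin_px, h_img - margin_px - h
    lo_x, hi_x = margin_px, w_img - margin_px - w
    if hi_y < lo_y or hi_x < lo_x:
        raise GeometryError("ROI plus margin does not fit at the image corners")
    return [(lo_y, lo_x), (lo_y, hi_x), (hi_y, lo_x), (hi_y, hi_x)]


def corner_background(
    projection: np.ndarray, roi: NucleusROI, margin_px: int = 2
) -> float:
    """Mean of four corner-ROI means, each corner ROI being the nucleus mask
    translated so its bounding box sits ``margin_px`` from that corner."""
    img = np.asarray(projection, dtype=float)
    ys, xs = np.nonzero(roi.mask)
    bbox = (ys.min(), xs.min(), ys.max() + 1, xs.max() + 1)
    local_y, local_x = ys - bbox[0], xs - bbox[1]
    corner_means = []
    for oy, ox in _corner_offsets(img.shape, bbox, margin_px):
        corner_means.append(img[local_y + oy, local_x + ox].mean())
    return float(np.mean(corner_means))


def nuclear_pmad(
    pmad_projection: np.ndarray,
    roi: NucleusROI,
    margin_px: int = 2,
    specimen_id: str = "",
    batch_id: str = "",
    animal_id: str = "",
    cytoplasm_mask: np.ndarray | None = None,
) -> PMadMeasurement:
    """Mean nuclear pMad over the ROI, corrected by the four-corner background.

    ``cytoplasm_mask`` optionally adds a descriptive cytoplasmic mean (used
    qualitatively for constructs that mislocalize pMad); it takes no part in
    normalization.
    """
    img = np.asarray(pmad_projection, dtype=float)
    if img.shape != roi.mask.shape:
        raise GeometryError("ROI mask shape does not match image shape")
    raw = float(img[roi.mask].mean())
    background = corner_background(img, roi, margin_px)
    cyto = None
    if cytoplasm_mask is not None:
        cyto = float(img[np.asarray(cytoplasm_mask, dtype=bool)].mean()) - background
    return PMadMeasurement(
        raw_nuclear_mean=raw,
        background_mean=background,
        corrected=raw - background,
        specimen_id=specimen_id,
        batch_id=batch_id,
        animal_id=animal_id,
        cytoplasm_mean=cyto,
    )


def aggregate_by_animal(
    measurements: Sequence[PMadMeasurement],
) -> list[PMadMeasurement]:
    """Average the corrected signal of neurons within each animal.

    The assay images three ddaC neurons per animal (segments A4-A6); using
    the animal as the statistical unit avoids pseudo-replication.  Call sites
    that want neurons as units simply skip this step.
    """
    by_animal: dict[tuple[str, str], list[PMadMeasurement]] = {}
    for m in measurements:
        by_animal.setdefault((m.animal_id or m.specimen_id, m.batch_id), []).append(m)
    out = []
    for (animal, batch), group in by_animal.items():
        out.append(
            PMadMeasurement(
                raw_nuclear_mean=float(np.mean([m.raw_nuclear_mean for m in group])),
                background_mean=float(np.mean([m.background_mean for m in group])),
                corrected=float(np.mean([m.corrected for m in group])),
                specimen_id=animal,
                batch_id=batch,
                animal_id=animal,
            )
        )
    return out


def normalize_to_control(
    experimental: Sequence[PMadMeasurement],
    control: Sequence[PMadMeasurement],
) -> NormalizedPMad:
    """Percent change of the experimental group mean relative to co-processed
    controls: ``100 * (mean_exp - mean_ctrl) / mean_ctrl``.

    Both groups must come from the same staining batch — immunosignal levels
    are only comparable within a staining solution.
    """
    if not experimental or not control:
        raise ValidationError("both groups must be nonempty")
    batches = {m.batch_id for m in experimental} | {m.batch_id for m in control}
    if len(batches) > 1:
        raise ValidationError(
            f"experimental and control span multiple staining batches: {batches}"
        )
    mean_ctrl = float(np.mean([m.corrected for m in control]))
    if mean_ctrl <= 0:
        raise ValidationError(
            f"control mean corrected signal must be positive, got {mean_ctrl}"
        )
    mean_exp = float(np.mean([m.corrected for m in experimental]))
    return NormalizedPMad(
        percent_change=100.0 * (mean_exp - mean_ctrl) / mean_ctrl,
        n_control=len(control),
        n_experimental=len(experimental),
        batch_id=batches.pop(),
    )
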
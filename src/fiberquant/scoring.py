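"""Perimeter-fraction dystrophin scoring on segmented sections.

The quantification follows a fixed recipe: laminin-positive pixels come
from a multi-level Otsu mask; one dystrophin pixel threshold is derived
per image set (exposure batch) as the mean over images of 1.5x the 99.8th
percentile of non-sarcolemmal dystrophin signal; each fiber's perimeter
band is scored as dystrophin-positive perimeter length over
laminin-positive perimeter length; a fiber is dystrophin positive when
that fraction reaches the cutoff (default 30%, inclusive).  Counts are
pooled across a section's images before the percentage is taken, and
intensity ratios are pooled weighted by laminin mask area.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.morphology import disk

from .segmentation import FiberLabelMap
from .synthetic import SectionImage

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.30
PERCENTILE = 99.8
MULTIPLIER = 1.5


@dataclass
class PositivityCutoff:
    """Perimeter fraction at or above which a fiber counts as positive."""

    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if not 0 < self.cutoff <= 1:
            raise ValueError("cutoff must be in (0, 1]")


@dataclass
class ThresholdSet:
    """One dystrophin-positive pixel threshold per image set."""

    per_image_p998: dict[str, float]
    multiplier: float = MULTIPLIER
    exposure_batch: str = "batch0"

    @property
    def set_threshold(self) -> float:
        vals = np.array(list(self.per_image_p998.values()))
        return float(self.multiplier * vals.mean())


@dataclass
class FiberScore:
    fiber_id: int
    laminin_perimeter: int                     # laminin-positive band pixels
    dystrophin_perimeter: int                  # supra-threshold band pixels
    fraction: float
    positive: bool


@dataclass
class SectionScore:
    n_total: int
    n_positive: int
    percent_positive: float
    intensity_ratio: float | None = None
    percent_of_control: float | None = None
    control_fallback_used: bool = False


# --------------------------------------------------------------------------
# Masks and thresholds
# --------------------------------------------------------------------------

def laminin_mask(laminin: np.ndarray, classes: int = 3,
                 positive_classes: int | str = "auto") -> np.ndarray:
    """Multi-level Otsu laminin mask.

    With ``positive_classes="auto"`` (default) the positive set is the
    classes above the multi-Otsu level closest to the bimodal Otsu
    threshold — the level that actually separates the bright wall
    network from tissue background, whichever cluster the remaining
    level happens to subdivide.  An integer keeps that many top classes
    instead.  Images with fewer distinct values than requested classes
    fall back to plain Otsu; constant images are an error.  The mask is
    invariant under positive intensity scaling.
    """
    laminin = np.asarray(laminin, dtype=float)
    if laminin.max() == laminin.min():
        raise ValueError("constant image: no threshold derivable")
    n_distinct = len(np.unique(laminin))
    if n_distinct <= classes:
        return laminin > threshold_otsu(laminin)
    thresholds = threshold_multiotsu(laminin, classes=classes)
    if positive_classes == "auto":
        anchor = threshold_otsu(laminin)
        t = thresholds[int(np.argmin(np.abs(thresholds - anchor)))]
        return laminin > t
    return laminin > thresholds[classes - 1 - int(positive_classes)]


def derive_threshold(images: list[SectionImage], masks: list[np.ndarray],
                     dilate_radius: int = 3,
                     percentile: float = PERCENTILE,
                     multiplier: float = MULTIPLIER) -> ThresholdSet:
    """Set-level dystrophin threshold from non-sarcolemmal background.

    Per image, the non-sarcolemmal region is the complement of the
    laminin mask dilated by ``dilate_radius`` pixels; the 99.8th
    percentile (linear interpolation) of dystrophin intensity there is
    recorded.  The set threshold is the mean over images of multiplier
    times that percentile.  Images from different exposure batches are
    refused.
    """
    if len(images) != len(masks) or not images:
        raise ValueError("need one mask per image, at least one image")
    batches = {im.exposure_batch for im in images}
    if len(batches) > 1:
        raise ValueError(f"mixed exposure batches {sorted(batches)}: images "
                         "acquired under different settings must not share a threshold")
    per_image: dict[str, float] = {}
    for i, (im, mask) in enumerate(zip(images, masks)):
        non_sarc = ~ndimage.binary_dilation(mask, structure=disk(dilate_radius))
        if not non_sarc.any():
            raise ValueError(f"image {im.sample_id}: empty non-sarcolemmal region")
        p = float(np.percentile(im.dystrophin[non_sarc], percentile))
        per_image[f"{im.sample_id}#{i}"] = p
    return ThresholdSet(per_image_p998=per_image, multiplier=multiplier,
                        exposure_batch=batches.pop())


# --------------------------------------------------------------------------
# Fiber scoring
# --------------------------------------------------------------------------

def perimeter_band(region: np.ndarray, halfwidth: int = 2) -> np.ndarray:
    """Band of +-halfwidth pixels around a fiber region's boundary.

    A square (chebyshev) structuring element keeps the band width uniform
    along walls of any orientation, so the band samples the perimeter
    evenly and the perimeter fraction is not biased by wall direction.
    """
    se = np.ones((2 * halfwidth + 1,) * 2, dtype=bool)
    return ndimage.binary_dilation(region, structure=se) \
        & ~ndimage.binary_erosion(region, structure=se)


def score_fibers(image: SectionImage, label_map: FiberLabelMap,
                 lam_mask: np.ndarray, thresholds: ThresholdSet,
                 cutoff: PositivityCutoff | float = DEFAULT_CUTOFF,
                 band_halfwidth: int = 2) -> list[FiberScore]:
    """Score each retained fiber's perimeter-fraction positivity.

    For each fiber the perimeter band is extracted; the laminin-positive
    pixels in the band define the fiber's perimeter length and the
    supra-threshold dystrophin pixels in the band its dystrophin-positive
    length.  Fractions above 1 (dystrophin band wider than laminin band)
    are clamped to 1.  Fibers with no laminin-positive perimeter are
    dropped with a warning.
    """
    if isinstance(cutoff, (int, float)):
        cutoff = PositivityCutoff(float(cutoff))
    if thresholds.exposure_batch != image.exposure_batch:
        raise ValueError(
            f"threshold from batch {thresholds.exposure_batch!r} applied to "
            f"image from batch {image.exposure_batch!r}")
    thr = thresholds.set_threshold
    dys_pos = image.dystrophin >= thr
    scores: list[FiberScore] = []
    for k in label_map.retained_ids():
        band = perimeter_band(label_map.labels == k, band_halfwidth)
        lam_px = int((band & lam_mask).sum())
        if lam_px == 0:
            warnings.warn(f"fiber {k}: no laminin-positive perimeter; dropped")
            continue
        dys_px = int((band & dys_pos).sum())
        frac = min(dys_px / lam_px, 1.0)
        scores.append(FiberScore(fiber_id=k, laminin_perimeter=lam_px,
                                 dystrophin_perimeter=dys_px, fraction=frac,
                                 positive=frac >= cutoff.cutoff))
    return scores


def pool_section(per_image_scores: list[list[FiberScore]]) -> SectionScore:
    """Pool positive/total fiber counts across a section's images.

    The percentage is computed on the pooled counts, never as the mean of
    per-image percentages.
    """
    if not per_image_scores:
        raise ValueError("need at least one image")
    n_total = sum(len(s) for s in per_image_scores)
    n_positive = sum(sum(f.positive for f in s) for s in per_image_scores)
    if n_total == 0:
        logger.warning("zero scored fibers: percent positive undefined")
        return SectionScore(n_total=0, n_positive=0, percent_positive=float("nan"))
    return SectionScore(n_total=n_total, n_positive=n_positive,
                        percent_positive=100.0 * n_positive / n_total)


# --------------------------------------------------------------------------
# Intensity analysis
# --------------------------------------------------------------------------

def intensity_ratio(image: SectionImage, lam_mask: np.ndarray) -> tuple[float, int]:
    """Dystrophin:laminin mean-intensity ratio under the laminin mask.

    Returns the ratio and the mask pixel count (the weight for pooling).
    """
    if not lam_mask.any():
        raise ValueError("empty laminin mask")
    lam_mean = float(image.laminin[lam_mask].mean())
    if lam_mean == 0:
        raise ValueError("zero mean laminin intensity under mask")
    dys_mean = float(image.dystrophin[lam_mask].mean())
    return dys_mean / lam_mean, int(lam_mask.sum())


def pool_intensity(ratios_and_areas: list[tuple[float, int]]) -> float:
    """Area-weighted mean of per-image intensity ratios."""
    if not ratios_and_areas:
        raise ValueError("need at least one image")
    ratios = np.array([r for r, _ in ratios_and_areas], dtype=float)
    areas = np.array([a for _, a in ratios_and_areas], dtype=float)
    if areas.sum() == 0:
        raise ValueError("zero total laminin mask area")
    return float((ratios * areas).sum() / areas.sum())


def percent_of_control(sample_ratio: float, control_ratios: list[float],
                       fallback_controls: list[float] | None = None
                       ) -> tuple[float, bool]:
    """Express a sample's intensity ratio as % of the control mean.

    When the matched-muscle control list is empty, the fallback list's
    mean is used and the result is flagged (second return value True).
    """
    fallback_used = False
    controls = list(control_ratios)
    if not controls:
        if not fallback_controls:
            raise ValueError("no control ratios and no fallback controls")
        controls = list(fallback_controls)
        fallback_used = True
        logger.info("matched controls unavailable; fallback control mean used")
    return 100.0 * sample_ratio / float(np.mean(controls)), fallback_used


def cardiac_intensity(image: SectionImage, control_ratios: list[float],
                      lam_mask: np.ndarray | None = None,
                      fallback_controls: list[float] | None = None
                      ) -> tuple[float, bool]:
    """Intensity-only readout for heart sections (no fiber segmentation).

    Mean dystrophin over mean laminin under the laminin mask, expressed
    as a percentage of the control mean.
    """
    if lam_mask is None:
        lam_mask = laminin_mask(image.laminin)
    ratio, _ = intensity_ratio(image, lam_mask)
    return percent_of_control(ratio, control_ratios, fallback_controls)


# --------------------------------------------------------------------------
# Overlay export
# --------------------------------------------------------------------------

OVERLAY_CMAP = "viridis"


def export_overlay(image: SectionImage, label_map: FiberLabelMap,
                   scores: list[FiberScore], band_halfwidth: int = 2
                   ) -> np.ndarray:
    """Color-coded heatmap of per-fiber perimeter fractions.

    Each fiber's perimeter band is painted with the viridis colormap
    mapped linearly over 0-100% positivity; background stays black.
    Returns an RGB uint8 array (use ``imageio`` to write it).
    """
    import matplotlib

    h, w = label_map.labels.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    cmap = matplotlib.colormaps[OVERLAY_CMAP]
    for s in scores:
        band = perimeter_band(label_map.labels == s.fiber_id, band_halfwidth)
        color = (np.array(cmap(s.fraction)[:3]) * 255).astype(np.uint8)
        rgb[band] = color
    return rgb


def decode_overlay_fraction(color: np.ndarray, n_samples: int = 256) -> float:
    """Invert the documented overlay colormap (nearest colormap entry)."""
    import matplotlib

    cmap = matplotlib.colormaps[OVERLAY_CMAP]
    grid = np.linspace(0, 1, n_samples)
    table = (np.array([cmap(g)[:3] for g in grid]) * 255)
    idx = int(np.argmin(((table - np.asarray(color, dtype=float)) ** 2).sum(axis=1)))
    return float(grid[idx])
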
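"""Fiber label maps from the laminin channel, or imported from external tools.

A classical substitute for learned fiber segmentation: the laminin ridge
network is thresholded, closed into a connected wall, and the enclosed
regions become fibers.  Any externally produced integer label map that
satisfies the same contract can be imported instead.  Objective QC flags
replace visual exclusion of badly segmented images.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk

logger = logging.getLogger(__name__)


@dataclass
class FiberLabelMap:
    """Integer-labeled fiber regions (0 = background/sarcolemma)."""

    labels: np.ndarray
    n_fibers: int
    excluded_fiber_ids: set[int] = field(default_factory=set)
    qc_status: str = "manual"                  # pass | fail | manual

    def __post_init__(self) -> None:
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        if len(present) != self.n_fibers:
            raise ValueError("n_fibers inconsistent with label map")

    def retained_ids(self) -> list[int]:
        present = sorted(set(np.unique(self.labels)) - {0})
        return [k for k in present if k not in self.excluded_fiber_ids]


def _relabel_connected(labels: np.ndarray) -> tuple[np.ndarray, bool]:
    """Split disconnected parts of a label into distinct fibers.

    Returns the consecutive relabeling and whether any label was split.
    """
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    split = False
    for k in sorted(set(np.unique(labels)) - {0}):
        comp, n = ndimage.label(labels == k)
        if n > 1:
            split = True
        for c in range(1, n + 1):
            out[comp == c] = next_id
            next_id += 1
    return out, split


def segment_fibers(laminin: np.ndarray, min_fiber_area: float = 100.0,
                   exclude_border: bool = True) -> FiberLabelMap:
    """Segment fibers as regions enclosed by the laminin wall network.

    The laminin-positive wall is Otsu-thresholded (scale invariant) and
    morphologically closed; connected components of its complement that do
    not contain an image corner are fibers.  Sub-minimum-area and
    (optionally) border-touching fibers are excluded and relabeled 0.
    """
    laminin = np.asarray(laminin, dtype=float)
    if laminin.size == 0 or laminin.max() == laminin.min():
        return FiberLabelMap(labels=np.zeros(laminin.shape, dtype=np.int32),
                             n_fibers=0, qc_status="fail")
    thr = threshold_otsu(laminin)
    wall = laminin > thr
    # edge-replicating pad: closing must not erode wall pixels that run
    # into the image border (a 1-px leak would merge adjacent fibers)
    padded = np.pad(wall, 1, mode="edge")
    wall = ndimage.binary_closing(padded, structure=disk(1))[1:-1, 1:-1]
    comp, _ = ndimage.label(~wall)

    h, w = laminin.shape
    # the outer non-tissue region spans several image corners; a fiber
    # straddling the border touches at most one
    corners = [comp[0, 0], comp[0, -1], comp[-1, 0], comp[-1, -1]]
    corner_labels = {c for c in set(corners) - {0} if corners.count(c) >= 2}
    border = np.zeros_like(comp, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(comp[border])) - {0}

    labels = np.zeros((h, w), dtype=np.int32)
    excluded: set[int] = set()
    next_id = 1
    for k in sorted(set(np.unique(comp)) - {0} - corner_labels):
        region = comp == k
        area = int(region.sum())
        if area < min_fiber_area:
            continue  # too small to be a fiber at all; not listed
        labels[region] = next_id
        if exclude_border and k in border_labels:
            excluded.add(next_id)
        next_id += 1
    n = next_id - 1
    return FiberLabelMap(labels=labels, n_fibers=n, excluded_fiber_ids=excluded,
                         qc_status="pass" if n else "fail")


def import_label_map(path_or_array, laminin: np.ndarray) -> FiberLabelMap:
    """Import an externally produced integer label map.

    Validates shape and integer dtype, splits disconnected labels into
    distinct fibers (with a warning), and relabels consecutively.
    """
    if isinstance(path_or_array, np.ndarray):
        raw = path_or_array
    else:
        raw = tifffile.imread(str(path_or_array))
    if raw.shape != np.asarray(laminin).shape:
        raise ValueError(f"label map shape {raw.shape} does not match image "
                         f"shape {np.asarray(laminin).shape}")
    if not np.issubdtype(raw.dtype, np.integer):
        if not np.allclose(raw, np.round(raw)):
            raise ValueError("label map must contain integer labels")
        raw = np.round(raw).astype(np.int64)
    if raw.min() < 0:
        raise ValueError("labels must be non-negative")
    labels, split = _relabel_connected(raw.astype(np.int32))
    if split:
        warnings.warn("imported label map contained disconnected labels; "
                      "parts were relabeled as distinct fibers")
        logger.warning("disconnected labels split during import")
    n = int(labels.max())
    return FiberLabelMap(labels=labels, n_fibers=n,
                         qc_status="pass" if n else "fail")


@dataclass
class QCReport:
    fiber_area_fraction: float
    median_solidity: float
    low_coverage_fiber_fraction: float
    status: str
    reasons: list[str] = field(default_factory=list)


def qc_segmentation(label_map: FiberLabelMap, laminin: np.ndarray,
                    min_area_fraction: float = 0.05,
                    min_median_solidity: float = 0.8,
                    max_low_coverage_fraction: float = 0.5,
                    coverage_cutoff: float = 0.5) -> QCReport:
    """Objective segmentation quality flags.

    An image fails when fibers cover too little area, fibers are grossly
    non-convex, or too many fiber boundaries lack laminin coverage (each
    checked against a configurable limit).  Failed images are excluded
    from downstream pooling.
    """
    laminin = np.asarray(laminin, dtype=float)
    labels = label_map.labels
    reasons: list[str] = []

    area_frac = float((labels > 0).mean())
    if area_frac < min_area_fraction:
        reasons.append(f"fiber area fraction {area_frac:.3f} < {min_area_fraction}")

    props = regionprops(labels)
    solidity = float(np.median([p.solidity for p in props])) if props else 0.0
    if solidity < min_median_solidity:
        reasons.append(f"median solidity {solidity:.3f} < {min_median_solidity}")

    low_cov = 1.0
    if props and laminin.max() > laminin.min():
        lam_thr = threshold_otsu(laminin)
        lam_mask = laminin > lam_thr
        n_low = 0
        for p in props:
            region = labels == p.label
            boundary = ndimage.binary_dilation(region, disk(2)) & ~region
            cov = lam_mask[boundary].mean() if boundary.any() else 0.0
            if cov < coverage_cutoff:
                n_low += 1
        low_cov = n_low / len(props)
    if low_cov > max_low_coverage_fraction:
        reasons.append(f"{low_cov:.0%} of fibers have boundary laminin "
                       f"coverage < {coverage_cutoff:.0%}")

    status = "fail" if reasons else "pass"
    return QCReport(fiber_area_fraction=area_frac, median_solidity=solidity,
                    low_coverage_fiber_fraction=low_cov, status=status,
                    reasons=reasons)
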
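"""Gel/blot lane densitometry: band AUC, transcript fractions, blot ratios.

RT-PCR transcript species (Dup2, WT, Δ2) are quantified as each band's
area under the lane profile as a percentage of the three-band total.
Immunoblot dystrophin (upper doublet) is normalized to the α-actinin
loading control; technical replicates of a sample collapse to their
median, control replicates to their mean, and the result is expressed as
a percentage of the wild-type control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import LaneProfile

logger = logging.getLogger(__name__)

RTPCR_BAND_ORDER = ("Dup2", "WT", "D2")   # largest product migrates least


@dataclass
class BandQuant:
    band_name: str
    window: tuple[float, float]
    area: float


@dataclass
class TranscriptFractions:
    pct_dup2: float
    pct_wt: float
    pct_d2: float

    @property
    def pct_therapeutic(self) -> float:
        return self.pct_wt + self.pct_d2

    def __post_init__(self) -> None:
        total = self.pct_dup2 + self.pct_wt + self.pct_d2
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"percentages sum to {total}, not 100")


@dataclass
class BlotResult:
    replicate_ratios: list[float]
    sample_ratio: float
    control_ratio: float
    percent_of_wt: float
    load_correction: float = 1.0


def integrate_band(profile: LaneProfile, window: tuple[float, float],
                   band_name: str = "", baseline: str = "none") -> BandQuant:
    """Numerical band area over a window, with optional linear baseline.

    ``baseline='linear'`` subtracts the chord between the window
    endpoints (the manual baseline of gel-analysis practice); the area is
    floored at 0.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("inverted or empty window")
    x = np.asarray(profile.positions, dtype=float)
    y = np.asarray(profile.intensities, dtype=float)
    sel = (x >= lo) & (x <= hi)
    if not sel.any():
        raise ValueError("window outside profile range")
    xs, ys = x[sel], y[sel]
    if baseline == "linear":
        # chord between the window edges; each endpoint is a short local
        # average so single-sample noise does not tilt the baseline
        k = min(5, max(1, len(ys) // 8))
        lo_val, hi_val = ys[:k].mean(), ys[-k:].mean()
        lo_pos, hi_pos = xs[:k].mean(), xs[-k:].mean()
        ys = ys - np.interp(xs, [lo_pos, hi_pos], [lo_val, hi_val])
    elif baseline != "none":
        raise ValueError(f"unknown baseline mode: {baseline!r}")
    area = float(np.trapezoid(ys, xs))
    return BandQuant(band_name=band_name, window=(lo, hi), area=max(area, 0.0))


def transcript_fractions(bands: dict[str, BandQuant]) -> TranscriptFractions:
    """Each species' band area as % of the three-band total."""
    missing = set(RTPCR_BAND_ORDER) - set(bands)
    if missing:
        raise ValueError(f"missing bands: {sorted(missing)}")
    total = sum(bands[n].area for n in RTPCR_BAND_ORDER)
    if total <= 0:
        raise ValueError("total band area is zero")
    pct = {n: 100.0 * bands[n].area / total for n in RTPCR_BAND_ORDER}
    return TranscriptFractions(pct_dup2=pct["Dup2"], pct_wt=pct["WT"],
                               pct_d2=pct["D2"])


def blot_quantify(sample_replicates: list[tuple[float, float]],
                  control_replicates: list[tuple[float, float]],
                  load_correction: float = 1.0) -> BlotResult:
    """Dystrophin/actinin ratios -> % of wild type.

    Each replicate is a (dystrophin_auc, actinin_auc) pair.  Sample
    replicates collapse to their median ratio, control replicates (2-3
    technical replicates expected) to their mean; percent of WT is
    ``100 * load_correction * sample_ratio / control_ratio``.  The load
    correction defaults to 1 and should be set to control_load /
    sample_load when loading masses differ.
    """
    if not sample_replicates:
        raise ValueError("need at least one sample replicate")
    if not control_replicates:
        raise ValueError("need at least one control replicate")

    def ratio(pair: tuple[float, float]) -> float:
        dys, act = pair
        if act <= 0:
            raise ValueError("actinin area must be > 0")
        return dys / act

    rep = [ratio(p) for p in sample_replicates]
    ctrl = [ratio(p) for p in control_replicates]
    sample_ratio = float(np.median(rep))
    control_ratio = float(np.mean(ctrl))
    if control_ratio <= 0:
        raise ValueError("control ratio must be > 0")
    pct = 100.0 * load_correction * sample_ratio / control_ratio
    return BlotResult(replicate_ratios=rep, sample_ratio=sample_ratio,
                      control_ratio=control_ratio, percent_of_wt=pct,
                      load_correction=load_correction)


def flag_failed_lanes(profiles: list[LaneProfile],
                      min_fraction_of_median: float = 0.2) -> list[str]:
    """Flag lanes with unusually low total intensity (failed transfer).

    A lane is excluded when its total intensity falls below the
    configured fraction of the batch median total.
    """
    if not profiles:
        return []
    totals = np.array([float(np.sum(p.intensities)) for p in profiles])
    median = float(np.median(totals))
    flagged = [p.lane_id for p, t in zip(profiles, totals)
               if t < min_fraction_of_median * median]
    for lane in flagged:
        logger.warning("lane %s flagged: total intensity below %.0f%% of batch median",
                       lane, 100 * min_fraction_of_median)
    return flagged


def extract_lane_profile(gel_image: np.ndarray, lane_rect: tuple[int, int, int, int],
                         lane_id: str = "lane0") -> LaneProfile:
    """Column-average a lane rectangle (row0, row1, col0, col1) of a gel image.

    The migration axis runs along rows; the rectangle comes from
    configuration, mirroring a manually drawn lane box.
    """
    r0, r1, c0, c1 = lane_rect
    if not (0 <= r0 < r1 <= gel_image.shape[0] and 0 <= c0 < c1 <= gel_image.shape[1]):
        raise ValueError("lane rectangle outside image")
    prof = np.asarray(gel_image, dtype=float)[r0:r1, c0:c1].mean(axis=1)
    return LaneProfile(positions=np.arange(r0, r1, dtype=float),
                       intensities=prof, lane_id=lane_id)
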
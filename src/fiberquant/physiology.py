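"""Muscle force physiology: CSA, specific force, eccentric force drop, outliers.

Physiological cross-sectional area is mass / (density x fiber-length
ratio x optimal length) with muscle density 1.06 mg/mm^3 and a
fiber-length ratio of 0.6 for the tibialis anterior; dividing absolute
tetanic force by CSA gives specific force.  Eccentric series are 10
tetanic peak forces under repeated 10%-of-L_o stretches, normalized to
the first contraction.  Outliers are removed once per group using a
+-1 SD screen (strict inequality, sample SD); for eccentric data the
10th normalized recording is the screening value and removal drops the
whole series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MUSCLE_DENSITY_MG_MM3 = 1.06
TA_FIBER_LENGTH_RATIO = 0.6


def cross_sectional_area(mass_mg: float | None = None, L_o_mm: float = 0.0,
                         density: float = MUSCLE_DENSITY_MG_MM3,
                         ratio: float = TA_FIBER_LENGTH_RATIO,
                         mass_g: float | None = None) -> float:
    """CSA in mm^2 = mass [mg] / (density x fiber-length ratio x L_o [mm]).

    Mass may be given in mg or in g (converted internally); exactly one
    must be provided.
    """
    if (mass_mg is None) == (mass_g is None):
        raise ValueError("provide exactly one of mass_mg or mass_g")
    if mass_g is not None:
        mass_mg = mass_g * 1000.0
    if mass_mg <= 0 or L_o_mm <= 0 or density <= 0 or ratio <= 0:
        raise ValueError("all inputs must be > 0")
    return mass_mg / (density * ratio * L_o_mm)


def specific_force(absolute_force_mN: float, csa_mm2: float) -> float:
    """Specific force in mN/mm^2."""
    if csa_mm2 <= 0:
        raise ValueError("csa must be > 0")
    if absolute_force_mN < 0:
        raise ValueError("force must be >= 0")
    return absolute_force_mN / csa_mm2


def eccentric_normalize(forces) -> np.ndarray:
    """Normalize a force series to its first contraction, in percent.

    Idempotent: normalizing an already-normalized series (first entry
    100) returns it unchanged.
    """
    forces = np.asarray(forces, dtype=float)
    if forces.size == 0:
        raise ValueError("empty force series")
    if forces[0] <= 0:
        raise ValueError("first force must be > 0")
    return 100.0 * forces / forces[0]


@dataclass
class OutlierResult:
    kept: list
    removed: list
    mean: float
    sd: float


def remove_outliers(values, screening_values=None,
                    min_group_size: int = 3) -> OutlierResult:
    """Single-pass +-1 SD outlier screen on a group of measurements.

    The group mean and sample SD (n-1 denominator) are computed once on
    the screening statistic; entries strictly more than one SD from the
    mean are removed.  ``screening_values`` lets a different statistic
    screen the entries (for eccentric series, the 10th normalized
    recording screens the whole series).  Groups smaller than
    ``min_group_size`` are returned unchanged with a warning.
    """
    values = list(values)
    screen = np.asarray(values if screening_values is None else screening_values,
                        dtype=float)
    if screen.ndim != 1 or len(screen) != len(values):
        raise ValueError("screening values must be one scalar per entry")
    if len(values) < min_group_size:
        logger.warning("group of %d too small for outlier screening; kept as is",
                       len(values))
        return OutlierResult(kept=values, removed=[],
                             mean=float("nan"), sd=float("nan"))
    mean = float(screen.mean())
    sd = float(screen.std(ddof=1))
    keep = np.abs(screen - mean) <= sd          # strict '>' removal
    removed = [v for v, k in zip(values, keep) if not k]
    kept = [v for v, k in zip(values, keep) if k]
    if removed:
        logger.info("removed %d of %d entries as +-1 SD outliers",
                    len(removed), len(values))
    return OutlierResult(kept=kept, removed=removed, mean=mean, sd=sd)


def remove_eccentric_outliers(series_list, screening_index: int = 9,
                              min_group_size: int = 3) -> OutlierResult:
    """Screen eccentric series on the 10th normalized recording.

    Each series is normalized to its first contraction; the recording at
    ``screening_index`` (default the 10th) is the screening statistic,
    and removal drops the entire series.
    """
    normalized = [eccentric_normalize(s) for s in series_list]
    screen = [s[screening_index] for s in normalized]
    return remove_outliers(normalized, screening_values=screen,
                           min_group_size=min_group_size)


ECC_COLUMNS = [f"ecc_force_{i}_mN" for i in range(1, 11)]


def process_physiology_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add CSA, specific force, and normalized eccentric series to a table.

    Expects columns sample_id, group, mass_mg, Lo_mm, absolute_force_mN
    and optionally ecc_force_1..10_mN.
    """
    out = df.copy()
    out["csa_mm2"] = [cross_sectional_area(mass_mg=m, L_o_mm=l)
                      for m, l in zip(df["mass_mg"], df["Lo_mm"])]
    out["specific_force_mN_mm2"] = out["absolute_force_mN"] / out["csa_mm2"]
    if all(c in df.columns for c in ECC_COLUMNS):
        norm = np.vstack([eccentric_normalize(row)
                          for row in df[ECC_COLUMNS].to_numpy(dtype=float)])
        for i in range(10):
            out[f"ecc_norm_{i + 1}_pct"] = norm[:, i]
    return out
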
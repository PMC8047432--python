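"""Dose-trend and group-comparison statistics for pipeline outputs.

Implements the study-style battery: one-way ANOVA with a post hoc test
for linear trend over dose-ordered groups, Kruskal-Wallis with Dunn's
pairwise post hoc comparisons, two-way (group x step) ANOVA with
Holm-Sidak-adjusted per-step contrasts for eccentric force series, and
the small-sample guard that skips inference when any group has n <= 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

STAR_LEVELS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")]


def p_to_stars(p: float) -> str:
    for level, stars in STAR_LEVELS:
        if p < level:
            return stars
    return "ns"


@dataclass
class DoseGroupTable:
    """Per-group measurements, groups ordered by dose (left to right)."""

    group_labels: list[str]
    values: list[np.ndarray]
    endpoint: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if len(self.group_labels) != len(self.values):
            raise ValueError("labels and value lists must align")
        if len(self.group_labels) < 2:
            raise ValueError("need >= 2 groups")
        self.values = [np.asarray(v, dtype=float) for v in self.values]

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, group_order: list[str],
                  value_col: str = "value", group_col: str = "group",
                  endpoint: str = "", units: str = "") -> "DoseGroupTable":
        vals = [df.loc[df[group_col] == g, value_col].to_numpy(dtype=float)
                for g in group_order]
        return cls(group_labels=list(group_order), values=vals,
                   endpoint=endpoint, units=units)


@dataclass
class TrendResult:
    slope: float            # contrast estimate per unit group rank
    t_stat: float
    df: int
    p_value: float
    stars: str = ""

    def __post_init__(self) -> None:
        self.stars = p_to_stars(self.p_value)


def trend_coefficients(k: int) -> np.ndarray:
    """Equally spaced centered contrast coefficients over group rank."""
    c = np.arange(k, dtype=float)
    return c - c.mean()


def anova_linear_trend(table: DoseGroupTable,
                       coefficients: np.ndarray | None = None) -> TrendResult:
    """One-way ANOVA with a post hoc test for linear trend, left to right.

    The trend contrast uses equally spaced centered coefficients over the
    group order (log-dose spacing can be passed explicitly).  The test
    statistic is t = sum(c_i * mean_i) / sqrt(MSE * sum(c_i^2 / n_i))
    with the one-way ANOVA residual df = N - k, two-sided p.
    """
    groups = table.values
    k = len(groups)
    n = np.array([len(g) for g in groups])
    if (n == 0).any():
        raise ValueError("every group needs at least one value")
    N = int(n.sum())
    if N <= k:
        raise ValueError("need N > k observations for a residual variance")
    c = trend_coefficients(k) if coefficients is None else np.asarray(coefficients, float)
    if abs(c.sum()) > 1e-9:
        raise ValueError("contrast coefficients must sum to zero")
    means = np.array([g.mean() for g in groups])
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    mse = sse / (N - k)
    estimate = float((c * means).sum())
    # normalize slope to per-unit-rank scale: estimate / sum(c * rank)
    slope = estimate / float((c * np.arange(k)).sum())
    if mse == 0:
        if abs(estimate) > 0:
            logger.warning("zero residual variance with nonzero contrast; p = 0")
            return TrendResult(slope=slope, t_stat=np.inf, df=N - k, p_value=0.0)
        return TrendResult(slope=0.0, t_stat=0.0, df=N - k, p_value=1.0)
    se = np.sqrt(mse * (c ** 2 / n).sum())
    t = estimate / se
    p = 2.0 * sps.t.sf(abs(t), N - k)
    return TrendResult(slope=slope, t_stat=float(t), df=N - k, p_value=float(p))


@dataclass
class DunnResult:
    h_stat: float
    h_p_value: float
    comparisons: list[tuple[str, str]]
    z_stats: list[float]
    p_adjusted: list[float]


def kruskal_dunn(table: DoseGroupTable,
                 comparisons: list[tuple[str, str]] | None = None) -> DunnResult:
    """Kruskal-Wallis H with Dunn's post hoc z tests over requested pairs.

    Dunn z uses mean ranks with the tie correction; the family of
    requested pairs is Bonferroni-adjusted (Dunn's procedure).  With all
    observations identical, H = 0 and every adjusted p is 1.
    """
    groups = table.values
    labels = table.group_labels
    if comparisons is None:
        comparisons = [(labels[i], labels[j]) for i in range(len(labels))
                       for j in range(i + 1, len(labels))]
    pooled = np.concatenate(groups)
    N = len(pooled)
    if np.all(pooled == pooled[0]):
        return DunnResult(h_stat=0.0, h_p_value=1.0, comparisons=comparisons,
                          z_stats=[0.0] * len(comparisons),
                          p_adjusted=[1.0] * len(comparisons))
    h_stat, h_p = sps.kruskal(*groups)
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    n_by: dict[str, int] = {}
    start = 0
    for lab, g in zip(labels, groups):
        mean_rank[lab] = float(ranks[start:start + len(g)].mean())
        n_by[lab] = len(g)
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (N - 1)))
    var_base = N * (N + 1) / 12.0 - tie_term
    m = len(comparisons)
    zs, ps = [], []
    for a, b in comparisons:
        se = np.sqrt(var_base * (1.0 / n_by[a] + 1.0 / n_by[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        zs.append(float(z))
        ps.append(min(1.0, float(p) * m))
    return DunnResult(h_stat=float(h_stat), h_p_value=float(h_p),
                      comparisons=comparisons, z_stats=zs, p_adjusted=ps)


def holm_sidak(p_values: list[float]) -> list[float]:
    """Step-down Sidak adjustment; adjusted p's are monotone in the ordering."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        a = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running_max = max(running_max, a)
        adj[idx] = min(1.0, running_max)
    return adj.tolist()


@dataclass
class TwoWayResult:
    anova_table: pd.DataFrame
    steps: list
    per_step: pd.DataFrame          # step, group_a, group_b, t, p_raw, p_adj, stars
    repeated_measures: bool = False
    notes: list[str] = field(default_factory=list)


def twoway_holm_sidak(df: pd.DataFrame, value_col: str = "value",
                      group_col: str = "group", step_col: str = "step",
                      subject_col: str | None = None) -> TwoWayResult:
    """Two-factor (group x step) ANOVA with Holm-Sidak per-step contrasts.

    Per step, every group pair is compared with a t contrast on the cell
    means using the full model's residual mean square; raw p values are
    Holm-Sidak adjusted within each step's family.  When no subject
    identifiers are given the factors are treated as independent (a
    logged caveat); with subject IDs the subject factor absorbs
    between-subject variance (repeated-measures style).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df.rename(columns={value_col: "y", group_col: "grp", step_col: "stp"})
    data = data.copy()
    data["grp"] = data["grp"].astype(str)
    data["stp"] = data["stp"].astype(str)
    notes = []
    repeated = subject_col is not None
    if repeated:
        data["subj"] = df[subject_col].astype(str).values
        formula = "y ~ C(grp) * C(stp) + C(subj)"
    else:
        notes.append("no subject IDs supplied: independent-factor two-way ANOVA")
        logger.info(notes[-1])
        formula = "y ~ C(grp) * C(stp)"
    fit = smf.ols(formula, data=data).fit()
    anova_tab = sm.stats.anova_lm(fit, typ=2)

    mse = fit.mse_resid
    dfr = int(fit.df_resid)
    steps = sorted(data["stp"].unique(), key=lambda s: (len(s), s))
    rows = []
    for stp in steps:
        sub = data[data["stp"] == stp]
        grps = sorted(sub["grp"].unique())
        if len(grps) < 2:
            raise ValueError(f"step {stp}: fewer than 2 groups observed")
        raw = []
        pairs = []
        for i in range(len(grps)):
            for j in range(i + 1, len(grps)):
                a = sub.loc[sub["grp"] == grps[i], "y"].to_numpy()
                b = sub.loc[sub["grp"] == grps[j], "y"].to_numpy()
                se = np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b)))
                t = (a.mean() - b.mean()) / se if se > 0 else 0.0
                p = 2.0 * sps.t.sf(abs(t), dfr) if se > 0 else 1.0
                pairs.append((grps[i], grps[j], float(t)))
                raw.append(float(p))
        adj = holm_sidak(raw)
        for (ga, gb, t), pr, pa in zip(pairs, raw, adj):
            rows.append({"step": stp, "group_a": ga, "group_b": gb, "t": t,
                         "p_raw": pr, "p_adj": pa, "stars": p_to_stars(pa)})
    per_step = pd.DataFrame(rows)
    return TwoWayResult(anova_table=anova_tab, steps=steps, per_step=per_step,
                        repeated_measures=repeated, notes=notes)


@dataclass
class GuardDecision:
    analyzed: bool
    reason: str = ""
    offending_groups: list[str] = field(default_factory=list)


def small_n_guard(table: DoseGroupTable, min_n: int = 4) -> GuardDecision:
    """Skip inference when any group has n <= 3 (low statistical power)."""
    offenders = [lab for lab, v in zip(table.group_labels, table.values)
                 if len(v) < min_n]
    if offenders:
        reason = (f"groups {offenders} have n <= {min_n - 1}; "
                  "dataset not statistically analyzed")
        logger.info(reason)
        return GuardDecision(analyzed=False, reason=reason,
                             offending_groups=offenders)
    return GuardDecision(analyzed=True)
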
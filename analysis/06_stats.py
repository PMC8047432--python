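#!/usr/bin/env python
"""Dose-trend and group-comparison statistics on the pipeline outputs.

Runs the study-style battery on the synthetic study: linear trend over
dose for IF positivity and transcript fractions, Kruskal-Wallis/Dunn on
specific force, two-way ANOVA with Holm-Sidak on the eccentric series,
and the n<=3 guard.  Writes results/06_stats.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DOSE_DESIGN, RESULTS

from fiberquant import stats as fqs

DOSES = list(DOSE_DESIGN)


def main() -> None:
    phys = pd.read_csv(RESULTS / "04_physiology.csv")
    rows = []

    table = fqs.DoseGroupTable.from_tidy(
        phys, DOSES, value_col="specific_force_mN_mm2", group_col="group",
        endpoint="specific force", units="mN/mm2")
    guard = fqs.small_n_guard(table)
    if guard.analyzed:
        trend = fqs.anova_linear_trend(table)
        rows.append({"endpoint": "specific_force", "test": "linear_trend",
                     "statistic": trend.t_stat, "p": trend.p_value,
                     "stars": trend.stars})
        dunn = fqs.kruskal_dunn(table, comparisons=[("vehicle", "high")])
        rows.append({"endpoint": "specific_force", "test": "kruskal_dunn",
                     "statistic": dunn.z_stats[0], "p": dunn.p_adjusted[0],
                     "stars": fqs.p_to_stars(dunn.p_adjusted[0])})

    ecc = phys.melt(id_vars=["sample_id", "group"],
                    value_vars=[f"ecc_norm_{i}_pct" for i in range(1, 11)],
                    var_name="step", value_name="value")
    ecc["step"] = ecc["step"].str.extract(r"(\d+)").astype(int)
    two = fqs.twoway_holm_sidak(ecc, subject_col="sample_id")
    last = two.per_step[two.per_step["step"] == "10"]
    for _, row in last.iterrows():
        rows.append({"endpoint": "eccentric_step10",
                     "test": f"holm_sidak {row['group_a']} vs {row['group_b']}",
                     "statistic": row["t"], "p": row["p_adj"],
                     "stars": row["stars"]})

    small = fqs.DoseGroupTable(group_labels=["a", "b"],
                               values=[[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
    rows.append({"endpoint": "n3_example", "test": "small_n_guard",
                 "statistic": float("nan"),
                 "p": float("nan"),
                 "stars": "skipped" if not fqs.small_n_guard(small).analyzed
                 else "analyzed"})

    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "06_stats.csv", index=False)
    print(out.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
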
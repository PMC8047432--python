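#!/usr/bin/env python
"""Score the synthetic sections blind and compare with ground truth.

Re-generates each section from the recorded seed, runs preprocessing,
segmentation, set-threshold derivation and perimeter-fraction scoring,
pools counts per dose, and writes recovered vs true positivity and
intensity to results/02_if_scores.csv.
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DOSE_DESIGN, RESULTS, SECTIONS_PER_DOSE, dose_seed

from fiberquant import preprocess as pp
from fiberquant import scoring as sc
from fiberquant import segmentation as seg
from fiberquant import synthetic as syn


def main() -> None:
    truth = pd.read_csv(RESULTS / "01_ground_truth.csv")
    rows = []
    for dose, (mean_frac, conc, _, _) in DOSE_DESIGN.items():
        per_image, ratios = [], []
        for i in range(SECTIONS_PER_DOSE):
            seed = dose_seed(dose, i)
            rng = np.random.default_rng(seed)
            a, b = mean_frac * conc, (1 - mean_frac) * conc
            fractions = rng.beta(a, b, size=100).tolist()
            image, _ = syn.generate_section(syn.SectionSpec(
                n_fibers=100, per_fiber_dystrophin_fraction=fractions,
                seed=seed))
            pre = pp.preprocess_section(image)
            fmap = seg.segment_fibers(pre.laminin)
            lam_mask = sc.laminin_mask(pre.laminin)
            thresholds = sc.derive_threshold([pre], [lam_mask])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                per_image.append(sc.score_fibers(pre, fmap, lam_mask,
                                                 thresholds))
            ratios.append(sc.intensity_ratio(pre, lam_mask))
        pooled = sc.pool_section(per_image)
        sub = truth[truth["dose"] == dose]
        rows.append({
            "dose": dose,
            "n_fibers": pooled.n_total,
            "percent_positive": pooled.percent_positive,
            "true_percent_positive": 100 * sub["true_n_positive"].sum()
            / sub["n_fibers"].sum(),
            "intensity_ratio": sc.pool_intensity(ratios),
            "true_intensity_ratio": sub["true_intensity_ratio"].mean(),
        })
    out = pd.DataFrame(rows)
    out["pct_error_points"] = (out["percent_positive"]
                               - out["true_percent_positive"]).abs()
    out.to_csv(RESULTS / "02_if_scores.csv", index=False)
    print(out.round(3).to_string(index=False))
    print(f"\nmax positivity error: {out['pct_error_points'].max():.2f} points")


if __name__ == "__main__":
    main()
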
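# fiberquant

Quantification pipeline for dystrophin-restoration studies in dystrophic
muscle: perimeter-fraction scoring of dystrophin/laminin
immunofluorescence, gel and immunoblot densitometry, muscle force
physiology, exon-2-skipping transcript logic, and dose-trend statistics —
exercised end to end on synthetic data with exact ground truth.

## Who this is for

Groups analyzing exon-skipping or gene-therapy experiments in muscle need
the same small set of readouts over and over: what fraction of fibers
re-express dystrophin at the sarcolemma, how much protein and which
transcripts are present, and whether muscle function recovers with dose.
This package implements those quantification procedures as a tested
library, and ships a synthetic-data module that renders sections, gel
lanes and force series with known truth so every stage can be validated
without microscope time.

## The core quantification

**Dystrophin-positive fiber scoring.** Muscle fibers are outlined by a
laminin ring (the basement membrane); dystrophin, when restored, appears
on a portion of that ring (the sarcolemma). After shading correction,
rolling-ball background subtraction and denoising, fibers are segmented
from the laminin channel; laminin-positive pixels come from a multi-level
Otsu mask. A single dystrophin pixel threshold is derived per image set:

    T = mean over images of [ 1.5 × P99.8(dystrophin | non-sarcolemmal pixels) ]

Each fiber is then scored as

    f = (dystrophin-positive perimeter length) / (laminin-positive perimeter length)

and called dystrophin positive when `f ≥ 0.30` (inclusive). Positive and
total counts are pooled across a section's images before the percentage
is taken. Dystrophin intensity is additionally summarized as the
dystrophin:laminin mean-intensity ratio under the laminin mask, pooled
weighted by mask area and expressed as a percent of matched controls.

**Densitometry.** RT-PCR lanes carry three possible products — Dup2
(two copies of exon 2, 340 bp), wild type (one copy, 278 bp) and Δ2
(zero copies, 216 bp). Each band's area under the lane profile is
reported as a percent of the three-band total; the therapeutic fraction
is WT + Δ2 (the Δ2 frameshift is rescued by the exon-5 IRES, which
starts translation in exon 6). Immunoblot dystrophin (upper doublet) is
normalized to α-actinin; sample replicates collapse to their median,
control replicates to their mean, and results are percent of wild type.

**Physiology.** Cross-sectional area is
`CSA = mass[mg] / (1.06 mg/mm³ × 0.6 × L_o[mm])`; specific force is
absolute tetanic force over CSA. Eccentric series (10 contractions,
10 % of L_o stretch per step) are normalized to the first contraction;
outliers are removed once per group when more than ±1 SD from the group
mean, screening eccentric series on the 10th recording.

**Statistics.** One-way ANOVA with a post hoc linear-trend contrast over
dose order, Kruskal–Wallis with Dunn's pairwise comparisons, two-way
(group × step) ANOVA with Holm–Sidak per-step contrasts, and a guard
that skips inference when any group has n ≤ 3.

## Worked example

```python
from fiberquant import preprocess, scoring, segmentation, synthetic

spec = synthetic.SectionSpec(n_fibers=100, seed=0)
image, truth = synthetic.generate_section(spec)

pre = preprocess.preprocess_section(image)
fibers = segmentation.segment_fibers(pre.laminin)
lam_mask = scoring.laminin_mask(pre.laminin)
thresholds = scoring.derive_threshold([pre], [lam_mask])
scores = scoring.score_fibers(pre, fibers, lam_mask, thresholds)
pooled = scoring.pool_section([scores])
ratio, _ = scoring.intensity_ratio(pre, lam_mask)

print(f"{pooled.n_positive}/{pooled.n_total} fibers positive "
      f"({pooled.percent_positive:.1f}%), truth "
      f"{100 * truth.n_positive / truth.n_total:.1f}%")
print(f"intensity ratio {ratio:.3f}, truth {truth.true_intensity_ratio:.3f}")
```

Output:

```
77/100 fibers positive (77.0%), truth 76.0%
intensity ratio 0.425, truth 0.422
```

The section was rendered with uniformly random per-fiber perimeter
fractions; the pipeline recovers the pooled positivity within one fiber
and the background-free dystrophin:laminin signal ratio within 1 %.

A full synthetic dose-escalation study lives under `analysis/`: run
`01_simulate.py` through `06_stats.py` in order; each driver prints what
it found and writes its tables under `results/`.

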
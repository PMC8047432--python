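# Methods

This note documents the models, parameters and design choices behind
each stage of the pipeline, what the synthetic data does and does not
emulate, and the numerical conventions that matter for reproducing its
outputs.

## Synthetic sections

Fiber geometry is a Voronoi tessellation of seeded blue-noise points
(rejection-sampled with a minimum spacing of 0.75 fiber diameters)
inside an inner tissue rectangle. Each cell is eroded by the laminin
ring width (chebyshev metric, default 3 px), leaving the fiber interior;
the cell-minus-interior shell is that fiber's laminin ring, so every
fiber has a closed ring and adjacent fibers share a 2×ring-width wall.
With `border_margin = 0` the erosion treats the image edge as tissue, so
edge cells straddle the border as in real scans; the default margin
keeps all rings closed inside the frame.

Dystrophin is painted on one contiguous angular arc of each fiber's ring
(a scatter option distributes the same pixel count randomly). The lit
pixel count is the ceiling of fraction × ring pixels, so a fiber
requested exactly at a cutoff is never rendered below it; rendering
error is at most one ring pixel. Ground truth records the realized
pixel fraction, the positivity call, and the background-free signal
ratio (mean dystrophin minus background over mean laminin minus
background, on the clean ring) — the quantity a background-subtracted
measurement estimates.

Shading is a multiplicative quadratic bowl with a seeded off-center
axis, normalized to mean 1 (amplitude default 0.15, typical of
wide-field vignetting); noise is additive Gaussian clipped at zero
(default SD 30 AU against a 200 AU background, 1200 AU dystrophin and
1500 AU laminin signal — signal-to-noise typical of a well-exposed
10× epifluorescence capture). Default image scale is 1.28 μm/px on a
16-bit-unsigned convention.

What the generator does **not** emulate: point-spread blur, fiber-size
and shape pathology (central nuclei, splitting), autofluorescence
texture, staining gradients that correlate with structure, and any
dose–response biology. Passing recovery tests therefore demonstrates
the correctness of the measurement chain under controlled conditions,
not robustness to every real-tissue artifact; the mask-import path
exists so real segmentations from other tools can be scored.

## Preprocessing

Order: shading correction → rolling-ball background subtraction →
denoising, applied identically to both channels of every image in a
batch; there is no random component.

*Shading.* The illumination field is a robust quadratic surface fit:
ordinary least squares iterated three times, each round discarding
pixels more than one residual SD **above** the surface, so bright
structure (walls, arcs) cannot drag the estimate while dark pixels are
kept (shading is a multiplicative loss). A heavy-Gaussian-blur
estimator is available as an option but under-corrects near the image
boundary (in our tests it removes only ~40–50 % of a quadratic field's
range versus ~100 % for the robust fit), which is why the surface fit
is the default. The corrected image is rescaled to preserve the input
mean exactly, making the step equivariant under global intensity
scaling.

*Rolling ball.* Background is the grayscale opening with a disk of the
given radius (default 50 px ≈ 3–4 fiber diameters at 1.28 μm/px).
For radii ≥ 20 the image is pre-smoothed and block-averaged down by
radius/10, opened at the scaled radius, lightly blurred and resized
back — the standard shrink/roll/enlarge acceleration. Pre-smoothing
matters: a raw morphological envelope hugs the noise minima and
under-subtracts by roughly two noise SDs.

*Denoising.* Median filter, size 3, by default (edge-preserving; leaves
constant regions untouched); Gaussian optional.

## Segmentation

The laminin wall network is thresholded with Otsu's method (scale
invariant), closed with a 1-px disk after edge-replicating padding
(plain closing erodes wall pixels on the image border and the 1-px leak
merges adjacent fibers), and fibers are the connected components of the
complement. The outer non-tissue region is identified as any component
containing at least two image corners — a border-straddling fiber can
touch at most one. Components below the minimum area (default 100 px²)
are dropped; border-touching fibers are excluded from scoring by
default because a partial perimeter would bias the 30 % rule.

QC is objective and thresholded where the original workflow relied on
visual inspection: an image fails when fibers cover < 5 % of its area,
median fiber solidity is < 0.8, or more than half of the fibers have
boundary laminin coverage below 50 %; limits are configurable.

External label maps can be imported instead; disconnected labels are
split into distinct fibers with a warning and relabeled consecutively.

## Scoring

*Laminin mask.* Multi-level Otsu with 3 classes. The positive set is
chosen automatically as the classes above the multi-Otsu level closest
to the bimodal Otsu threshold. Rationale: with two intensity clusters,
one multi-Otsu level lands in the wall/background gap and the spare
level subdivides whichever cluster has more weighted variance — on some
images the wall cluster (top class then covers only part of the ring),
on others the zero-clipped background spike (top two classes then
swallow the noise tail). Anchoring on the bimodal threshold picks the
separating level in both regimes. A fixed number of top classes remains
available as an override.

*Set threshold.* Per image, the non-sarcolemmal region is the
complement of the laminin mask dilated by 3 px; the 99.8th percentile
(linear interpolation) of dystrophin intensity there is multiplied by
1.5, and the values are averaged across the image set. One threshold
per exposure batch, applied uniformly; mixing batches raises an error.
Thresholds are derived from preprocessed images so they are
illumination-independent.

*Perimeter band.* Each fiber's band is its region dilated minus eroded
by 2 px with a **square** structuring element. The square (chebyshev)
footprint matches the erosion metric that defines the ring, keeping the
band width uniform along walls of any orientation; a disk-shaped band
under-samples diagonal wall segments and biases fractions by several
percentage points. The fraction is supra-threshold dystrophin pixels
over laminin-positive pixels within the band, clamped to 1 (the
dystrophin band can be wider than the laminin band); the cutoff is
inclusive at 0.30. Fibers with no laminin-positive perimeter are
dropped with a warning.

*Pooling.* Counts are summed across images before the percentage is
taken (never a mean of percentages). Intensity ratios are pooled
weighted by laminin-mask area. Percent-of-control divides by the mean
of matched-muscle controls, falling back to a flagged alternative
control list when none exist. Heart sections use the intensity readout
only, without fiber segmentation.

*Overlay.* Perimeter bands are colored by fraction on viridis over
0–100 %; the colormap is documented so overlays can be decoded back to
fractions within one quantization step.

## Densitometry

Band areas are trapezoidal integrals over configured windows (default
±4σ around expected migration positions), floored at zero. The
optional linear baseline is the chord between the window edges, with
each endpoint averaged over ~5 samples so single-pixel noise cannot
tilt it. Transcript percentages divide by the three-band total and
therefore sum to 100 and are scale invariant. Blot quantification
divides the dystrophin doublet area by the α-actinin area per
replicate, takes the sample median and control mean, and reports
percent of wild type; an explicit load-correction factor (control load
over sample load) is available but defaults to 1 because loading
regimes differ between experiments and silently correcting would be
worse than documenting. Lanes whose total intensity falls below 20 %
of the batch median are flagged as failed transfers and excluded.

## Physiology

CSA uses muscle density 1.06 mg/mm³ and fiber-length ratio 0.6
(tibialis anterior); mass may be entered in mg or g and is reconciled
internally. Eccentric normalization divides by the first contraction
(idempotent by construction). The ±1 SD outlier screen runs exactly
once per group (not iterated), uses the sample SD (n−1), keeps boundary
values (strict inequality), refuses groups smaller than 3, and for
eccentric data screens on the 10th normalized recording, removing whole
series.

## Statistics

The linear-trend contrast uses equally spaced centered coefficients
over group order (log-dose spacing can be supplied explicitly);
t = Σcᵢx̄ᵢ / √(MSE Σcᵢ²/nᵢ) on N−k residual df, two-sided. With two
groups this reduces exactly to the pooled t test. Dunn's z uses mean
ranks with the tie correction; the requested family of pairs is
Bonferroni-adjusted (Dunn's original recommendation). Holm–Sidak is
the step-down Sidak with enforced monotonicity. The two-way
(group × step) analysis adds a subject factor when subject IDs are
provided, otherwise falls back to independent factors with a logged
caveat; per-step group contrasts use the full-model residual mean
square. Datasets with any group at n ≤ 3 are skipped with a report
naming the offending groups. Significance stars follow the usual
figure convention (\*, \*\*, \*\*\*, \*\*\*\* at 0.05, 0.01, 0.001,
0.0001).

Calibration of the trend test (null type-I error within
[0.035, 0.065] at α = 0.05 over 2,000 simulations, agreement with a
10⁴-permutation oracle) is asserted in the test suite and recomputed by
the acceptance script.

## Transcript logic

The three exon-2 species (Dup2/WT/Δ2) are enumerated from any gene
model containing the target exon. In-silico PCR finds each primer
exactly once on the spliced sequence and reports the product from the
forward primer's 5′ end to the reverse primer's 5′ end inclusive (both
footprints counted) — the three products always form an arithmetic
progression with common difference equal to the exon-2 length. Frame
analysis scans codons from the annotated start and reports the first
stop and its exon. The IRES rule is declarative, not a sequence-level
IRES finder: zero copies of exon 2 → IRES-dependent translation from
exon 6 (therapeutic); two copies → no rescue (not therapeutic); the
clinical evidence for the rule is outside what sequence analysis can
establish.

The bundled toy gene model is synthetic (engineered sequences, not the
human reference): four exons of 150/62/80/60 nt with the assay primers
embedded so the products are exactly 340/278/216 bp, and exon 3 opening
with a block that carries stop codons in both shifted reading frames
(placed by computing the actual reading phases, so the construction
holds for any exon-2 length) while leaving the wild-type frame open.
An exon-1 length of 150 nt is required: a junction-spanning reverse
primer caps the product at upstream-length + 142 bp, so no 100-nt
exon 1 can yield a 278-bp product.

## Problem sizes

Recovery suites run 20 sections of 100 fibers at 512² px for the
default-noise batch, single sections at 300–400² px for geometric
oracles, 2,000 simulations for type-I calibration and 10⁴ permutations
for the trend oracle; the acceptance script uses 12 sections and 1,000
null simulations. These sizes give Monte-Carlo error comfortably inside
every asserted tolerance.

## Known limitations

- The classical segmenter assumes a connected bright wall network; it
  is a substitute for learned segmentation, validated only on synthetic
  geometry. Real sections with broken staining should use the import
  path.
- Perimeter fractions measured through the band subsample the ring near
  three-way wall junctions; per-fiber deviations of a few tenths of a
  percentage point (occasionally ~1 point on small fibers) are expected
  even noise-free.
- The rolling-ball implementation is an approximation tuned for
  backgrounds varying on scales ≫ the structure width; it is not a
  pixel-exact reproduction of any particular vendor's filter.
- The equivalence of the preprocessing chain to the original
  proprietary implementations cannot be established — only functional
  equivalence (shading removed, background flattened, noise reduced) is
  claimed and tested.
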
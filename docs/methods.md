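# Methods

`phenolidar` analyses plot-segmented LiDAR point clouds from ground-based
scanning of wheat field trials, turning them into plot-level traits — crop
height, the 3D voxel index (3DVI) and the 3D profile index (3DPI) — and then
into the quantities a breeding programme cares about: per-event repeatability
(broad-sense heritability on a genotype-mean basis), genotype BLUPs, trait
correlations, and crop growth rate (CGR) over each genotype's stem-elongation
(GS31) to anthesis (GS65) window. Because no public plot-level data exist for
this kind of campaign, the package ships a synthetic field-trial generator
with fully known ground truth; every statistical claim the test suite makes
is a recovery or invariance statement against that truth.

## Trait extraction from point clouds

**Ground elevation.** Soil returns dominate the height histogram of a column
of plots (the scanning platform traverses the field column-wise, and inter-row
gaps plus canopy transmission always contribute soil returns). Heights are
binned at 0.01 m, bins anchored at integer multiples of the bin width; the
ground elevation is the mean height of the points in the modal bin, ties
breaking toward the lower bin. A single-plot fallback exists for standalone
use but pooling per column is the default, since a sparse single plot can
have too few soil returns.

**Crop height** is the mean of all returns at or above the 95th percentile of
the plot's height distribution (percentile by linear interpolation of order
statistics) minus the ground elevation. Returns within one ground bin of the
ground elevation are excluded before the percentile by default — whether soil
returns should enter the height distribution is an interpretation the source
description leaves open, so the exclusion band is configurable
(`exclude_ground`, `ground_band`). Heights within twice the noise tolerance
below zero clamp to 0; larger negatives clamp too but raise a data-quality
warning, since they indicate a wrong ground model.

**3DVI** voxelises the plot's canopy bounding volume — the plot rectangle's
footprint from the ground elevation to the highest canopy return — into
0.05 m cubes anchored at the rectangle corner and the ground elevation, and
reports occupied voxels over total voxels. Cells are half-open; a point on a
boundary belongs to the higher-index cell; partial top cells count fully in
the total. The index saturates as canopies fill their volume, which is its
known weakness under high biomass.

**3DPI** sums, over 0.01 m height layers from the ground to the top of the
canopy, the fractional interception of returns. The published one-sentence
definition ("fractional number of points intercepted") is ambiguous, so two
variants are implemented:

* `interception` (default): layers processed top-down, each layer's fraction
  being its returns over the beams not yet intercepted above it. This is a
  discrete gap-fraction profile; it is bounded by the number of layers and
  responds nearly linearly to green-area index under the Beer–Lambert canopy
  model below.
* `fraction_of_total`: each layer's returns over all returns including soil.
  This collapses to the canopy-return fraction (it is 1.0 whenever every
  return is in the canopy, regardless of arrangement) and is retained only
  because the published wording admits it; the degeneracy is asserted in the
  tests.

No layer weighting is applied in either variant.

## Crop growth rate

CGR for any trait is (value at GS65 − value at GS31) / days, per plot, in the
trait's units per day (t·ha⁻¹·day⁻¹ for AGB). Genotypes reach anthesis on
different calendar dates while scans occur on common dates, so trait values
are linearly interpolated between sampling events to each genotype's GS31 and
GS65 dates; a value is taken exactly from an event that coincides with the
phenology date. There is no extrapolation: plots whose event window does not
bracket the phenology window are excluded with a logged reason rather than
guessed at. Dates are ISO-8601 calendar dates and durations whole days.

## Random-effects analysis

Each trait × event is analysed separately under

    y = Xβ + Z_g u_g + Z_row u_row + Z_col u_col + ε

with independent random intercepts for genotype, field row and field column,
and an intercept (optionally plus a fixed second-order polynomial in centred
(row, col)) as X. This row/column model, with the optional smooth trend,
stands in for a P-spline spatial ANOVA surface; the substitution is validated
by recovery tests under the generator's spatial trend, which is deliberately
not of the fitted form (see below).

Variance components are estimated by REML via EM iterations to a relative
tolerance of 1e-8 (componentwise change scaled by the phenotypic variance,
at most 10,000 iterations). The EM update is a posterior expectation of a
non-negative quantity, so negative estimates cannot arise; components that
collapse numerically (below 1e-10 of the phenotypic variance) are pinned to
zero, which matches the convention of truncating negative variance estimates
at zero and reproduces the "repeatability exactly 0" outcomes seen in noisy
destructive data. Because plain EM converges geometrically — and very slowly
near the zero-variance boundary — the iteration applies Aitken Δ²
extrapolation to each component on a 10-iteration subsampled sequence,
jumping to the extrapolated limit (or the boundary) when the sequence is
monotone. The accelerated fit agrees with lme4's REML on crossed designs to
about 1e-4 in the components and 1e-6 in the BLUPs, which the test suite
asserts via an Rscript oracle.

From the fit: repeatability ρ = σ²g/(σ²g + σ²ε/nrep), clamped to [0, 1] and
defined as 0 when σ²g = 0; nrep is the arithmetic mean genotype replication
(harmonic available by option, relevant for partial-replicate designs whose
mean replication is fractional, e.g. 2.45 or 1.6). BLUPs are û_g = σ²g Z'g P y
(shrunken genotype means; they sum to ~0 and have no more variance than raw
genotype means). Correlations between BLUP vectors are Pearson over the
pairwise intersection of genotypes (not the genotypes common to all traits),
with two-sided p from the t distribution on n − 2 df and stars at
p < 0.0001/0.001/0.01/0.05. Intraclass correlation between two sampling
events is the correlation of that trait's BLUPs at the two events. Raw-data
regressions of AGB on an index are ordinary least squares on plot-level,
non-spatially-corrected values. p-values are reported unadjusted; no
multiple-testing correction is applied anywhere. Missing plot values are
dropped listwise per event; nothing is imputed.

Residual normality (Shapiro–Wilk W) and a variance-homogeneity ratio (upper
over lower half of the fitted-value range) are computed per trait × event and
logged as advisory diagnostics; they never gate the analysis, since no action
rule is defined for them.

## The synthetic field trial

The generator emulates the three structures such campaigns use: a 60-plot
RCBD (20 genotypes × 3 replicates), and partial-replicate designs of 240
plots / 98 genotypes (mean replication 2.45, range 1–4) and 64 plots / 41
genotypes (mean 1.6, range 1–2). Partial-replicate allocation gives every
genotype the floor of the budget share, distributes the remainder randomly,
then applies mean-preserving transfers within the stated range so replication
actually spans it. Plot rectangles are the *sampled* sections (default
6 rows × 0.18 m × 1.0 m = 1.08 m²), which is what both the quadrat harvest
and the LiDAR segmentation target.

**Genotypes** differ in maximum height (0.85 ± 0.08 m), peak green-area index
(5.0 × lognormal(0, 0.15)), developmental rate (×(1 ± 0.06)) and phenology
(GS31 at 80 ± 3 days after sowing; GS65 45 ± 3 days later). Canopy height and
green area follow a logistic in time — the simplest monotone saturating
growth law — pegged at 25% of the ceiling at GS31 (a first-node wheat canopy
is roughly a quarter of its final height) and 75% at GS65. Rate modifiers
pivot the curve at GS31, so slower growth lowers everything after stem
elongation. The `water_limited` scenario multiplies the rate by 0.6 and all
residual observation noise by 2 (documented constants for a qualitative
contrast).

**Spatial structure** is a smooth second-order polynomial over the field
(scale 0.04) plus independent row and column effects (sd 0.03), applied as a
multiplicative canopy anomaly. The statistics module fits additive row and
column effects, so its spatial model is deliberately only partially correct —
the recovery tests therefore exercise mild model misspecification, as any
real spatial adjustment does. Terrain slopes gently across columns and is
constant within a column, consistent with column-wise ground pooling.

**Scans** place a regular grid of nadir beams over the plot rectangle
(default 0.03 m spacing, ~1,200 beams per 1.08 m² plot — a desk-scale
density, far below a real scanner's, chosen so full multi-event trials
simulate in seconds). Each beam traverses 0.01 m canopy layers top-down and
is intercepted in a layer with probability 1 − exp(−k·d·Δz), with k = 0.5 the
canopy extinction coefficient and d the green-area density (GAI/height,
vertically uniform); otherwise it returns from the soil. A 5% fraction of
beams falls in permanent inter-row gaps. Every beam yields exactly one
return; z noise is Gaussian truncated at ±3 sd (0.005 m default), so returns
never fall below terrain − 3 sd.

**Destructive AGB** (t/ha) tracks canopy volume: the genotype ceiling is
(12 t/ha + an independent tissue-density effect with variance σ²g = 1.44)
× (height×GAI)/(reference height×reference GAI), following the same logistic.
Sampling noise has sd sqrt(2.4) ≈ 1.55 t/ha at a 1 m² reference quadrat,
scaling as 1/sqrt(quadrat area) — a 0.3 m² quadrat is about 1.9× noisier
(sd ≈ 2.8 t/ha, a ~20% CV at anthesis). These magnitudes were chosen so the
simulated repeatabilities of small-quadrat AGB fall in the ranges reported
for real trials (rising from ≈0.15–0.35 at stem elongation to ≈0.5–0.6 at
anthesis, and ≈0.3 for CGR); no published value for quadrat sampling noise
exists, so the scaling constant is a free generator parameter. **NDVI** is simulated as
0.15 + 0.75·(1 − exp(−0.5·GAI)) plus noise — a saturating surrogate with no
radiometric model.

What the generator does *not* emulate: occlusion correlations between
neighbouring beams, mixed pixels, organ-level structure, lodging, senescence
after anthesis, registration error, and any radiometry. Passing tests
therefore show that the pipeline recovers known truth under a plausible
canopy/sampling model — not that the indices are unbiased on real canopies.

## Reproducibility and numerical choices

All randomness flows through explicit integer seeds; child seeds are derived
with `numpy.random.SeedSequence.spawn`, so the same configuration and seed
reproduce every table byte-for-byte (reports are JSON with sorted keys; each
CSV carries the configuration hash in a header comment). Plot rectangles are
half-open so tiled plots never share points; voxel and layer assignment use
floor on (coordinate − origin)/size with the same half-open convention.
Degenerate inputs are signalled, not guessed at: empty plots raise a distinct
signal, constant responses yield an explicitly degenerate all-zero fit,
genotypes missing phenology are named in the error, and dates outside the
sampled window refuse to extrapolate.

Default problem sizes in the tests (trials of 40–60 plots, four sampling
events, ~1,200 beams per plot, 200–500 replicate simulations) are desk-scale
choices that keep full statistical recovery runs in the minutes range while
leaving every estimator in its asymptotically relevant regime.
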
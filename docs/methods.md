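# Methods

This note documents the models, conventions and numerical choices behind
`repeatmosaic`, in the order data flows through the package.

## Fragment sizing and modal-allele calling (`traceio`)

PCR across a tandem repeat yields a ladder of products separated by one
repeat unit (6 bp for a hexamer). Sizing is a linear map
`size_bp = intercept + slope · repeats` fitted by least squares to sizing
standards of known repeat length (defaults 37/44/50 units). A fitted slope
outside [5.5, 6.5] bp/repeat indicates the standards are inconsistent with a
hexameric unit and the calibration is rejected. The default intercept of
138 bp is a reconstruction of the constant flanking sequence consistent with
the anchors 330 bp ↔ 32 repeats and ≈560 bp ↔ 70 repeats; it is not a
measured flank length, and real assays should calibrate against their own
standards. Fragment sizes between 330 and 560 bp are standards-anchored;
outside that window repeat lengths are linear extrapolations ("molecular
weight" estimates) and are flagged, retained by default, and excludable from
indices by option.

Peaks are binned to the nearest integer repeat after calibration (robust to
sub-bp drift, rather than imposing a fixed 6 bp comb), colliding bins have
their heights summed (heights proxy molecule counts), and the modal allele
is the tallest bin. Modal ties break toward the smaller repeat — the
conservative choice against calling spurious expansion.

## Expansion index (`instability`)

With modal height `h0` and relative threshold `t` (default 0.05), peaks with
height < `t·h0` are discarded; retained heights (modal and both flanks) are
normalized to sum to one, and

* expansion index = Σ over retained peaks with Δ > 0 of weight × Δ,
* contraction index = the analogue over Δ < 0 with |Δ|,
* instability index = their sum,

where Δ is repeat distance from the trace's own modal allele (not a
genotyped reference). The normalization denominator is the sum of **all**
retained peaks, including the modal peak and the contraction side. This
denominator is the single most consequential convention in the package: the
index literature does not always restate it, alternatives (expansion-side-
only normalization) change values by a roughly constant factor, and the
brute-force oracle in the test suite pins the implemented definition
exactly. The threshold comparison is inclusive (height exactly at 5% of
modal is retained).

Indices are scale-invariant in the heights, zero for single-peak traces, and
strictly increase when an above-threshold expansion peak is added. For
autosomal loci with two alleles, the distribution is split at the midpoint
between the two declared modal peaks and each half is indexed independently;
alleles closer than 4 repeat units (configurable) are refused, since their
stutter/expansion flanks overlap and per-allele indices are not meaningful.

## Single-molecule SP-PCR (`smolecule`)

At limiting dilution the number of amplifiable molecules per well is
Poisson(λ), so the negative-well fraction estimates λ̂ = −ln(n₀/n). The 95%
interval is a Clopper–Pearson (exact binomial) interval on P(no product)
transformed through −ln; the exact interval is chosen because plates are
small (72 DNA wells) and the interval must behave at the boundaries. With
zero negative wells λ is unbounded above and the estimate is returned as a
flagged "too concentrated" result rather than a number. Titration selects
the dilution with negative fraction nearest 1/3 (λ ≈ ln 3 ≈ 1.1, at which
most positive wells are single-molecule); ties go to the more dilute member.

Plate QC fails on any positive no-DNA control, a negative DNA-well fraction
below 1/3, or a sized well under the minimum height (150 RFU); QC enumerates
reasons and never raises. Sized alleles are classified by sign of
(repeat − modal reference); the default reference is the SP-PCR modal allele
(most frequent sized length, ties to smaller), with the bulk-genotyping
modal usable instead. Magnitude bins are 1–4, ≥5 and ≥20 units per side,
with ≥20 nested inside ≥5. Cross-tissue comparisons use the Pearson χ² test
of independence on the R×3 contracted/modal/expanded table without
continuity correction, df = 2(R−1), warning when any expected cell is
below 5 (the standard validity guideline).

## Synthetic-data generator (`simcore`)

The generator's defaults encode the cohort conditions the package is
designed around, and every random draw flows through an explicit seed or
`numpy.random.Generator` (no global state).

**Cohort.** Inherited repeats ~ round(Normal(41.6, 3.9)) clipped to 30–55
units; AAO = 100 − 1.4·repeat + Normal(0, 6) years, truncated below at 12
years. With repeat SD 3.9 and residual SD 6.0 the population R² for the
repeat→AAO regression is 0.45 (σ = |b|·s_x·√((1−R²)/R²), exposed as
`noise_sd_for_r_squared`). Disease duration is drawn independently of repeat
length (Normal(9, 4) years, floored at 0.5), making duration a true null for
the duration regression; age at death is AAO + duration.

**Somatic change.** Per cell the repeat change Δ is a mixture: a point mass
at 0, geometric expansion and contraction tails (P(|Δ| = k) ∝ q^(k−1), so
most changes are 1–4 units), and a rare large-jump component with
|Δ| = 20 + Geometric(0.04) − 1, expansion-biased at 7:3 (large expansions
are observed several-fold more often than large contractions). Expansion
probability is linear in (inherited − 30) per the tissue's
`expansion_rate_per_unit`, clamped to 0 below the 30-unit reference (with a
warning) and capped silently once the total change probability reaches 1 —
the linear model saturates for the longest alleles in the most unstable
tissues. Contraction probability is length-independent. Repeats are floored
at 1 unit.

**Tissue panel.** The default eight tissues are ordered blood ≪ cerebellum
< caudate < putamen < hippocampus < cingulate gyrus < frontal BA9 <
occipital cortex, with rates and tails chosen so that end-to-end measured
median expansion indices at the default cohort land near the scale reported
for postmortem repeat-instability surveys (blood ≈ 0.2, cerebellum ≈ 0.7,
occipital cortex ≈ 1.1–1.6). Tissues carry a block label (blood /
subcortical / cortical); per-individual and per-block multiplicative
log-normal random effects (CV 0.25 each) make tissues of one block
correlate within an individual, which is what the heatmap clustering
recovers.

**Electropherogram.** Each true allele seeds a geometric stutter ladder
(minus rate 0.15, plus rate 0.02 by default) and is weighted by a
short-allele amplification advantage (1.02× per unit shorter than the modal
allele — the bulk-PCR contraction bias). Ladders are summed, jittered with
multiplicative log-normal noise (CV 0.1 by default; the mean is corrected so
jitter is unbiased), scaled to a modal height of 8000 RFU, and placed
exactly on the calibration line, so adjacent single-unit peaks are exactly
6 bp apart. Peaks below 10⁻⁴ of the maximum are dropped.

**Plates.** DNA wells draw Poisson(λ) molecules from the allele
distribution; empty wells are product-negative and no-DNA controls are
always negative. Wells with several molecules report only the shortest one
(the short template wins the amplification race) — a documented
simplification; real SP-PCR similarly cannot resolve co-amplified products,
and a sensitivity test shows class fractions shift by < 0.1 between λ = 0.1
and λ = 1.1.

**What the generator does not emulate:** germline transmission, age
dependence of mosaicism (no age term exists in the model), sequence-level
repeat structure or interruptions, cell-type heterogeneity within a tissue
piece, Southern-blot densitometry, and real trace artifacts (baseline noise,
off-ladder peaks, dye pull-up). Passing tests therefore demonstrate the
analysis stack is correct under a plausible generative model, not that the
biological parameter values are those of any real tissue.

## Cohort statistics (`cohortstats`)

Phenotype fits are ordinary least squares with the F-test p-value (identical
to the slope t-test for one predictor; both interpretations of figure-style
p-values coincide here). The Pearson/Spearman switch runs Shapiro–Wilk at
α = 0.05 on both variables and uses Pearson only if neither rejects; the
chosen method is always reported. Cross-locus comparison correlates
per-tissue mean indices over tissues shared by both loci (≥ 4 required)
with Pearson directly, since the inputs are a handful of means.

Pairwise tissue comparisons are two-sided Wilcoxon rank-sum
(Mann–Whitney) tests, Bonferroni-adjusted by the number of pairs in the run
(the family is all pairwise comparisons of one analysis), capped at 1.

The heatmap stage excludes tissues with fewer than 12 measurements and
individuals with fewer than 6 measured tissues (poor normalization
otherwise), z-scores each tissue column with ddof = 1 (the R `scale()`
convention, matching the field's R-based workflows), drops constant columns,
and clusters rows and columns by agglomerative average linkage on
pairwise-complete Manhattan distance, where each pair's summed |difference|
is rescaled by the fraction of entries observed in both (pairs with no
shared entries get twice the maximum observed distance, with a warning).
Average linkage is the package's choice where only the distance is
conventionally specified; the linkage method is exposed. Missing cells stay
missing in the returned matrix.

## Problem sizes in the test suite

The statistical acceptance tests run at the scales the checks were designed
for: 200 seeded cohorts of n = 266 for slope recovery/CI coverage, 1000
titrations for λ-interval coverage, 30 ten-individual cohorts for tissue
ordering, 20 cohorts of 23 individuals (the scale of a postmortem heatmap
after exclusions) for planted-block recovery, 100 runs of ~150 sized wells
for expansion-bias detection, and 300 cohorts of n = 68 for the duration
null. The full suite completes in well under the per-check minute budgets on
one CPU.

## Known limitations

* The expansion index depends on the threshold and denominator conventions
  above; values are comparable only across traces analyzed with the same
  settings.
* Extrapolated repeat lengths (outside 330–560 bp) inherit the calibration
  line's error, which grows with distance from the standards.
* The χ² comparison treats wells as independent; wells from the same plate
  share amplification conditions.
* Collision handling in simulated plates slightly enriches short alleles at
  high λ, mirroring (but not exactly modelling) real co-amplification bias.
* The clustering treats missingness as ignorable; systematically missing
  tissues (e.g. a region unavailable for the most affected individuals)
  would bias the distances.
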
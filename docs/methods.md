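# Methods

## Screen scoring model

A sensitization screen measures, per gene, nuclei counts in replicate
wells (default triplicate) under two arms: untreated and a low cisplatin
dose at the no-observed-effect level (NOEL), defined as the IC10 of a
fraction-affected dose-response curve. `estimate_noel` interpolates Fa
linearly on log10 dose between the first bracketing pair of observed
doses; an exact node is returned as-is, and a target outside the observed
Fa range is an error rather than an extrapolation.

Counts are aggregated by **median** across replicate wells so that one
failed well (e.g. a transfection failure) in a triplicate cannot move the
gene. All percentages live on the 0–100 scale. The reference for both the
Survival Index and the % survival with cisplatin is the *untreated*
RNAiMAX control-well median of the plates hosting the gene: normalizing
the drug arm to the no-drug reference is what makes the baseline drug
effect visible in the Difference. The normalization is per hosting plate
(set), which absorbs plate batch factors without relying on any
cross-plate pairing metadata.

The Difference is computed on the percentage scale (`SI − %survival`),
with the BRCA2 positive-control difference computed identically on the
same plates, so Potentiation is comparable across plates; a raw-count
mode (`difference_scale="count"`) is available. A failed positive control
(non-positive BRCA2 difference) is a hard error naming the problem, not a
silent NaN. The Gene Score `(100 − |SI − 100|) × Potentiation` is applied
literally, without clamping: SI > 200 makes the first factor negative and
sinks the gene in rank, which matches the statistic's intent. Ranking
breaks score ties by gene symbol ascending so ranks are a deterministic
permutation. The lethality boundary is inclusive (SI ≤ 30 — "at least 70%
loss"), the hit filter uses linearly interpolated percentiles (a constant
column passes every gene), and the DE shortlist cutoff is a strict
`p < alpha`; all three boundary conventions are pinned for
reproducibility.

## Plate-effect model

Positional and batch artifacts are modeled multiplicatively:
`count ≈ plate × row × column × gene`, i.e. additively on log counts.
Rather than an (unspecifiable) mixed-effects fit, the package uses the
robust screen-analysis standard: iterative median polish of row and
column effects on log counts, after first removing each (plate, arm)
median — that first step absorbs both batch level and the treatment
effect, so the positional sweep cannot confuse the drug with a column.
Plate factors come from the untreated reference-control medians after
positional adjustment. All three factor families are renormalized to
geometric mean 1 (identifiability). A `fitter` hook accepts a substitute
estimator (e.g. a REML mixed model) with the same return contract.

Known-effect control wells are excluded from the fit: the
transfection-efficiency control (near-empty by design) everywhere, and
the sensitization positive control in the drug arm (~50%-point planted
effect). Both classes are confined to the control columns, and leaving
them in measurably biases those columns' factors (and hence corrected
Survival Index, by about one percentage point in simulation).

Corrected counts are counts divided by the three factors; correction is
approximately idempotent (a refit on corrected data returns factors
within rounding of 1). Per-gene drug-vs-untreated inference uses Welch's
two-sided t on log counts with Benjamini–Hochberg adjustment. At
triplicate scale the Welch–Satterthwaite df approximation itself is
measurably non-uniform under the null (max CDF deviation ≈ 0.024 at 3v3,
≈ 0.006 at 6v6, by direct simulation); the null-calibration experiment in
the test suite therefore runs at 6 replicates per arm, and triplicate
Welch p-values should be treated as approximate.

## Expression stage

The stage ingests a gene-level log2 matrix; array summarization is out of
scope. Quantile normalization maps every column onto the row-wise mean of
the column-sorted matrix, interpolating tied values at their average
rank; it is idempotent. Sample QC is classical MDS (eigendecomposition of
the double-centered squared-distance matrix) with a robust-z
(median/MAD) flag on distance from the coordinate centroid.

The treated-vs-untreated contrast pools timepoints within arm (timepoint
is kept as metadata). The moderated t shrinks pooled per-gene variances
toward a common prior estimated by moment matching on `log s²`: the
excess of `var(log s²)` over `trigamma(df/2)` determines the prior df
`d0` (via the inverse trigamma), and the prior scale follows from the
mean. The posterior variance `(d0·s0² + df·s²)/(d0 + df)` feeds a t
statistic on `df + d0` degrees of freedom; a non-positive excess yields
infinite `d0` (fully shrunk, normal reference). With shrinkage disabled
the statistic equals the ordinary equal-variance two-sample t to machine
precision — that limit is the anchored contract. Zero-variance genes
(possible only in noise-free synthetic data) get p = 0 for a nonzero
fold-change and p = 1 otherwise. ddCt relative quantification is
`2^(−ΔΔCt)` against an endogenous control gene and calibrator sample.

## Integration and enrichment

DE genes join screen summaries on upper-cased symbols; unmatched genes
are returned, never dropped. The candidate filter keeps whole-genome
rank strictly below `rank_max` (default 2000). The two-sided Fisher test
enumerates the hypergeometric support and sums probabilities no larger
than the observed table's (relative tie tolerance 1e-7 against floating
evaluation of exact rational ties); scipy's implementation serves as an
independent oracle in the tests, not as the implementation. Gene-set
enrichment (GMT input) is upper-tail hypergeometric per set with an
optional BH column; the default universe is the set of screened genes.
Clonogenic validation reduces to plating efficiency
(`100 × colonies/seeded`) with Holm-adjusted pairwise Welch tests
(`pairwise_welch_holm`); Holm (plain, not Holm–Šidák) is the single
pinned step-down procedure shared with the yeast stage.

## Yeast fitness model

Fitness is the trapezoidal AUC of an OD600 curve over the full 24 h
horizon after subtracting the initial reading (the inoculation density,
≈0.07), expressed replicate-wise as a proportion of the mean wild-type
untreated AUC — replicate-wise so the t-test sees the real replicate
variance. Baseline subtraction makes a no-growth curve score exactly 0;
no growth-window trimming is applied (pinned choice). The multiplicative
null model predicts mutant-under-drug fitness as
`f_mutation × f_drug(WT)`; each strain's observed drug-arm replicates are
compared to that constant with a two-sided one-sample t, Holm-corrected
across strains. A strain significantly below expectation indicates a
synthetic-sick drug-gene interaction.

## Synthetic data: what it emulates, and what it does not

`simulate_screen` reproduces the screen's design: 384-well plates with
the four control classes randomly spotted in columns 1–4 at 24/16/8/16
wells per plate, triplicate gene wells per arm, 2000-cell-seeding
baseline counts, lognormal well noise (counts of order 10³ are dominated
by multiplicative variation, hence lognormal rather than Poisson),
multiplicative plate batch factors, independent row/column factors with
an extra border depression, a baseline drug effect `drug_fa` (default
0.1, the IC10 condition), a planted 50%-point positive-control
sensitization, and planted sensitizer/lethal genes. Both arms are
interleaved within each plate (control classes split evenly between
arms), which keeps every gene's reference and positive control on its own
plate. Independent seed substreams drive labels, layout, batch factors
and noise, so configurations differing only in effect sizes share noise
realizations — that is what makes "with effects vs without effects"
error comparisons meaningful at a fixed seed. Planted truth (per-gene
SI/sensitization/label, per-plate factors, positional surface) is emitted
alongside every dataset.

The generator's sensitization truth is the total expected Difference,
including the baseline drug effect; a *fully* null screen therefore sets
`drug_fa=0` along with zero effect fractions and noise, and passes
through scoring as SI = 100 and Potentiation = 0 exactly. The well-level
noise magnitudes are calibration choices (cv ≈ 0.1), not published
values. Not emulated: the imaging step, the multi-week cycle structure of
the real screen, spatially smooth (non-separable) artifacts beyond the
border ring, and siRNA off-target effects — so passing recovery tests
demonstrates correctness of the statistics, not robustness to every
failure mode of real screens.

`simulate_expression` plants fixed ±LFC shifts on uniform(6, 12)
baselines with Gaussian noise, 3 replicates × 2 timepoints × 2 arms.
`simulate_growth_curves` scales a common logistic growth increment
(carrying capacity 1.0 OD, rate 0.6/h, midpoint 8 h, 49 half-hour
readings over 24 h) by the strain/condition fitness, so the
baseline-subtracted AUC ratio equals the planted multiplier exactly at
zero noise; an `interactions` map plants sub-multiplicative drug-gene
interactions.

## Problem sizes and numerical choices in the test suite

Recovery experiments run at desk scale, chosen to keep the full suite
fast while leaving comfortable statistical margins: 500-gene screens
(10 plates) for rank-correlation (Spearman > 0.9 under a graded
"titration" of planted sensitization uniform on [0, 80] %-points) and for
the plate-correction error-reduction check; 1000-gene nulls for p-value
calibration; a 2000-gene expression matrix for the exact 101-up/50-down
shortlist recovery, run in the noise-free limit because any positive
noise level implies ~0.5% false positives at alpha = 0.005 and "exact"
recovery is then not a meaningful target; 100 seeds of two-strain yeast
experiments for interaction detection power. Degenerate inputs are
handled explicitly throughout: empty well sets, all-zero plates, zero
variances, constant percentile distributions, and replicate counts below
2 each raise or flag rather than propagate NaN.

## Known limitations

- The published screen's exact normalization of Potentiation is not
  recoverable from the printed per-gene table (implied positive-control
  differences vary between rows); both percent- and count-scale modes are
  provided and neither is asserted to be the published constant.
- The mixed-effects plate model of the original analysis is approximated
  by median polish; the `fitter` hook is the extension point.
- The moderated-t prior estimation uses moment matching, not the exact
  published empirical-Bayes estimator of any particular package; the
  zero-shrinkage limit is the tested contract.
- Enrichment is generic hypergeometric over user-supplied sets; curated
  commercial pathway collections and their p-values are out of scope.
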
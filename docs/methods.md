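# Methods

## Model and scope

`laneseq` treats the read count `X_ij` of gene *j* in lane *i* as Poisson
with `log E[X_ij] = log d_i + log λ_{a(i),j} (+ θ_i)`. The Poisson
assumption is appropriate for *technical* replicate lanes of one library;
it is knowingly wrong for biological replicates, where counts are
over-dispersed and a negative-binomial treatment would be needed — that is
out of scope here. Counts are whole-gene: no isoform-level quantification,
and exon-junction reads are not modelled (reads are genomic intervals).

## Normalization

All factor methods return `d` rescaled so `Σ d_i` equals the grand total
count; this keeps normalized measures on the counts-per-lane scale while
only the ratios `d_i/d_k` matter to the tests. Conceptually the `d` vector
*defines* the null hypothesis: a gene splitting its counts across lanes in
proportion to `d` is deemed non-DE.

* **Total-count**: `d_i` = column sums. Equivalent to the RPKM convention
  once divided by gene length (`per_length_measure`, reads per kb per
  million).
* **Housekeeping**: `d_i` = counts of one nominated gene; errors if that
  gene has a zero anywhere.
* **Upper-quartile**: 75th percentile of each lane's counts over genes with
  reads in at least one lane (zeros retained within a lane when a gene is
  expressed elsewhere). The quantile estimator is linear interpolation
  between order statistics (the common "type 7" convention); the estimator
  choice is fixed for determinism, not because the alternatives are wrong.
  The median is deliberately not offered as a factor: with the
  preponderance of zero/low counts it is uninformative about sequencing
  effort.
* **Quantile normalization**: per rank, the reference is the median across
  lanes of the lane-wise sorted counts; each lane's sorted counts are
  replaced by the reference and the matrix is rounded half-away-from-zero
  so the exact/likelihood tests still apply. Tie policy (`ties=`):
  `'first'` (default) assigns each tied entry its own rank's reference
  value with ranks broken by input order — normalized lanes then share the
  sorted reference vector exactly, and the procedure is idempotent to ±1
  per entry; `'mean'` gives a tie run the mean reference over its ranks,
  which treats equal counts symmetrically but lets long runs of tied low
  counts deviate from the common distribution. Genes with zero counts in
  every lane are excluded from the rank computation and stay zero.

## Differential-expression statistics

All two-group tests share a direction convention in the batch driver
(`run_de`): the sign of the estimated log-fold-change of the second sorted
condition relative to the first. A direction of 0 is never counted as a
positive call in benchmarking.

* **Poisson GLM + likelihood ratio.** Fitting is by IRLS (max 50
  iterations, coefficient-change tolerance 1e-10). For the intercept-only
  and condition designs the MLE is available in closed form (group count
  sum over group offset sum) and the iterative fit reproduces it to
  ~1e-10 relative; the batch driver uses the closed form directly for the
  plain two-group design, so 10⁴ genes fit in well under a second, and the
  iterative path serves the designs with flow-cell or library-prep terms.
  A zero-count group drives its coefficient to −∞; the fit clamps at −30
  on the log scale and flags `converged=False` rather than raising, since
  the LR statistic remains finite and meaningful. Supported designs:
  intercept-only; per-condition means; condition plus flow-cell contrasts;
  flow-cell means plus library-prep contrasts nested within flow-cell.
  Nesting for the LR test is verified by column-space containment, not by
  name.
* **t statistics.** The GLM t uses the observed-information covariance of
  the fit; the delta-method t works on pooled condition counts with
  variance `1/x_A + 1/x_B` (first-order variance of a log count ratio).
  For the plain two-group design the two coincide whenever both groups
  have reads; they differ in zero-count handling (huge-but-finite SE from
  the clamped fit vs an exactly infinite SE, reported as statistic 0,
  p = 1, flag `zero_count`). Both inherit the degeneracy that makes
  t statistics useless for zero-count genes — that behaviour is a finding,
  not a bug, and the low-count filter (`filter_low_count`, default: drop
  genes with fewer than 20 pooled reads in either condition, strictly
  fewer) exists to rescue them.
* **Fisher's exact test.** The 2×2 table is
  `[[x_A, x_B], [round(d_A)−x_A, round(d_B)−x_B]]` with `d` summed per
  condition and rounded to integers (an exact test needs integer margins).
  Two-sided p-values follow the minimum-likelihood rule — the sum of all
  hypergeometric point probabilities not exceeding the observed one — with
  the customary `1 + 1e-7` relative slack on the tie comparison, matching
  the behaviour of the standard R/scipy implementations. The p-values for
  a whole support are computed in one vectorized sorted-cumsum pass
  (`fisher_pvalues_for_margins`).
* **Cochran–Mantel–Haenszel.** One table per stratum (flow-cell by
  default), 1-df chi-square without continuity correction; the common
  direction comes from the Mantel–Haenszel pooled odds ratio. Strata with
  a zero margin carry no information and are dropped with a warning. The
  asymptotic CMH statistic was chosen over an exact stratified test, whose
  two-sided construction is not uniquely defined.
* **Length weighting.** `weight_by_length` divides a t statistic by
  `sqrt(length)` and recomputes the normal-reference p-value. Rationale:
  the t statistics' standard errors shrink like `1/sqrt(expected count)`,
  and expected counts grow with gene length, so at a common threshold long
  genes with small effects outrank short genes with large effects;
  `1/sqrt(length)` cancels the growth and yields a length-independent
  ranking. The alternative fixed-length reanalysis is supported through
  `sample_fixed_length` (a contiguous window in UI coordinate space,
  uniform start, seeded) and, for count matrices, binomial thinning with
  probability `L/length` (`resample_fixed_length_counts`), which is the
  distribution of the reads falling in such a window under uniform read
  placement.
* Benjamini–Hochberg adjusted p-values accompany every batch result
  (via `statsmodels.multipletests`).

## UI genes and read counting

A constitutive exon is a maximal run of bases present in every isoform of
a gene (base-level intersection, then maximal-interval merge); the UI gene
is the union of constitutive exons minus the union of *coding* exons of
all other genes — non-coding exons of neighbours do not mask. Genes whose
UI region is empty are omitted; genes whose transcripts span chromosomes
are reported and skipped. Coordinates are 0-based half-open internally;
GTF (1-based inclusive) is converted at the boundary, and a chromosome
allow-list is available but defaults to all.

Counting: a unique-mapping read is assigned to a UI gene when it overlaps
the gene's regions by at least one base, strands pooled, at most once per
gene; a read overlapping UI regions of two genes increments both and is
logged as ambiguous (UI construction makes this rare). Uniqueness is a
pluggable predicate for SAM input (default: primary alignment with mapping
quality > 0) and a score-column convention for BED, because "maps
uniquely" is mapper-specific.

## Benchmarking

Gold-standard genes are classed by absolute log-ratio: non-DE below `a`,
DE (signed) above `b`, no-call inside `[a, b]` (defaults `a = 0.2`,
`b = 2.0`); no-calls are ignored. The confusion rules are direction-aware:
a DE call on a gold-DE gene in the *wrong* direction is a false positive,
not a true positive or a false negative. TPR = TP / (gold DE genes);
FPR = FP / (gold non-DE genes). Because wrong-direction FPs arise from
gold-DE genes while N counts only gold non-DE genes, FPR can exceed 1 in
pathological constructions; the denominator convention is isolated in one
place. The ROC sweep runs over the observed p-values (exact step curve,
deterministic) and includes the origin and the everything-called endpoint.
The gold log-ratio base (natural log by default) must match the DE
estimates' base.

Goodness-of-fit: per gene, the offset-only Poisson model is fit to
replicate lanes (closed form: `μ̂_i = d_i · λ̂`) and the Pearson statistic
`Σ (x_i − μ̂_i)²/μ̂_i` is referred to χ² with (lanes − parameters) df;
deviance is available as an option, Pearson is the default as the standard
χ²-referenced choice. All-zero genes are excluded. The
`(FMM − FPM)/FMM` helper estimates a sequencing error rate from
purity-filtered perfectly-matching vs ≤2-mismatch read counts, assuming no
SNPs; it is undefined (returned as missing) when FMM = 0.

## The synthetic-data generator

`simgen` emulates a two-condition, two-flow-cell experiment with seven
lanes per condition and library preparation confounded with condition —
the layout the package's analyses are designed around. Defaults, chosen
once as the study conditions:

* 2,000 genes; fixed per-lane depth multipliers on an even grid spanning
  1 ± 0.2 (known targets for depth-recovery checks); expected 50 reads
  per gene per unit-depth lane, giving lane totals around 10⁵ — a
  deliberately scaled-down lane that keeps every simulation fast while
  preserving the count regime of interest.
* Baseline expression log-normal with log-scale sd 1.65. For a log-normal,
  the share of expected counts in the top 5% of genes is Φ(σ − 1.645),
  which equals 1/2 at σ = 1.645 — the generator reproduces the "few genes
  carry half the reads" skew by construction.
* DE effects are split symmetrically across conditions
  (`λ_A = λ e^{−lfc/2}`, `λ_B = λ e^{+lfc/2}`), so `λ` is the
  geometric-mean expression. Applying the whole effect to one condition
  would inflate that condition's totals and quantiles even for
  sign-balanced effects (since `E[e^lfc] > 1` and rank crossings are
  asymmetric), confounding normalization comparisons with a generator
  artefact.
* Technical effects are lane-level multipliers shared across genes (the
  simplest structure consistent with the model), off by default.
* Gene lengths log-uniform on [200, 10000] bp; the gold standard is the
  true log-fold-change plus Gaussian noise (sd 0.05).

Canned scenarios: `scenario_null` (depth differences only),
`scenario_basic_de` (10% DE, log-fold-change sd 1.5),
`scenario_highcount_bias` (top 5% of genes over-expressed in one direction
with log-fold-change 1.0, plus 10% sign-balanced DE of magnitude 2.5 to
populate the gold DE classes without shifting count quantiles), and
`scenario_length_bias` (expression proportional to length, lengths
log-uniform on [250, 5000] bp, pooled per-condition counts ≈ length in bp,
and a small effect of sd 0.3 in *every* gene — mimicking data in which no
gene is exactly null, the regime in which unweighted t statistics rank
long genes as more significant).

All draws come from one `numpy` generator per bundle in a fixed substream
order (lengths, expression, DE assignment, lane effects, counts, then
gold/reads), so a bundle is fully reproducible from its seed.

What the generator does *not* emulate: biological replicate variability
(no over-dispersion), sequence content and mappability, coverage
non-uniformity along genes, junction reads, and correlated technical
effects. Tests passing on these simulations therefore validate the
statistical machinery under its stated assumptions — they do not certify
performance on over-dispersed biological designs.

## Numerical conventions and degenerate inputs

* Counts are integers end to end; quantile-normalized output is rounded
  half-away-from-zero (a fixed rule for bit-stable output).
* IRLS divergence (zero-count cells) is detected by |coefficient| > 30 on
  the log scale, clamped and flagged — never an exception; per-gene
  failures in batch runs become flags, never aborts.
* A negative LR statistic beyond −1e-8 relative triggers a warning;
  small negatives are clipped to 0.
* Factor computations reject non-positive results (zero-total lanes,
  zero housekeeping counts, degenerate 75th percentiles) with the lane
  named in the error.
* Ties: quantile normalization as above; ROC thresholds collapse tied
  p-values into single sweep points; Fisher tie comparisons use the
  `1 + 1e-7` relative slack.
* Seeds are plain integers; every simulation entry point takes one
  explicitly.

## Test-suite problem sizes

The stochastic checks run at sizes chosen to make their Monte-Carlo bands
meaningful while keeping the whole suite quick: 10⁴ genes for type-I
calibration (3 SE band ≈ ±0.0065 around 0.05), 5×10³ genes × 7 lanes for
goodness-of-fit calibration (Kolmogorov–Smirnov against χ²₆), 2×10³ genes
for the normalization-bias scenario with the Monte-Carlo SE of the
null-median statistic estimated from replicate scenario draws (the naive
per-gene SE would ignore the quantile-factor noise shared by all genes),
10³ genes for the length-bias scenario, and an exhaustive enumeration of
all 2×2 tables with margins up to 200 (reduced by transpose/complement
symmetry) for exact-test correctness.
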
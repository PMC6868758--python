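# Methods

## Model and assumptions

The package treats a gene's expression as informative only relative to other
genes in the same sample. A small panel of *reference genes* — housekeeping
genes that are stably expressed across samples and conditions — defines, in
every sample, a ladder of expression levels. Each gene's position on that
ladder (its *tier*) is an ordinal value in [0, n] that does not change under
any strictly increasing transform applied to a whole sample. Library size,
scanner gain, log-scaling, probe saturation and similar sample-wise technical
effects are all (approximately) monotone, so tiers are the unit of analysis
for both differential expression and classification.

The key assumptions are:

* the chosen reference genes are expressed in every sample (a reference at
  zero leaves its tier boundary undefined — such genes are excluded from
  candidacy by an infinite product score);
* their biological variability is small relative to the spacing between them,
  so their within-sample ordering is stable (occasional rank inversions are
  tolerated by re-sorting boundaries per sample and are counted in the log);
* cross-platform use requires only that the same reference and biomarker
  genes are measured on both platforms; no distributional assumption is made
  about the measurements themselves.

## Normalization

RNA-seq counts are normalized with trimmed-mean-of-M-values (TMM) scale
factors and converted to counts per million (CPM). For each sample against a
reference sample (the one whose upper-quartile count fraction is closest to
the mean), per-gene log2 expression ratios (M) and average log intensities
(A) are computed over genes nonzero in both samples; the top and bottom 30%
of M and 5% of A are trimmed, and the factor is the precision-weighted mean
of the surviving M-values (weights = inverse delta-method binomial variance).
Factors are rescaled to geometric mean 1, and CPM = 1e6·count/(library ×
factor). This matches the edgeR implementation to ~7 significant digits
(verified against edgeR during development). Note that the precision weights
depend on library depth, so rescaling a single sample perturbs the factors
at the ~1e-3 level — exact invariance holds only for a global rescaling.
Pre-normalized microarray matrices bypass normalization entirely.

## Reference selection

Stability is scored per gene over all samples, conditions pooled:
COV = sd/mean (sample sd, n−1 denominator, a deliberate choice — the
definition does not fix the denominator and the difference is immaterial at
n ≥ 30), MFC = max/min, PS = COV·MFC. Candidates are housekeeping genes with
PS in the lowest 5% of all finite PS values and mean expression ≥ 1 CPM
(both configurable; the method itself prescribes "lowest product scores"
without a numeric cutoff).

The log2 mean-expression axis is divided into strata of the target spacing
(default 2.0 log2 units) *centred* on the lowest candidate — i.e., stratum =
round((x − x₀)/spacing). Centred strata were chosen over strata that start
at the lowest candidate because planted or real reference panels tend to sit
near integer multiples of the spacing; with edge-aligned strata every second
such gene lies exactly on a stratum boundary and sampling noise flips its
stratum assignment about half the time. The lowest-PS candidate of each
nonempty stratum is selected (ties by gene ID); a greedy farthest-point sweep
keeps the most evenly spaced `n_refs` when requested, and consecutive
selections closer than half the spacing are collapsed. For matrices already
on a log scale (auto-detected when the maximum value is below 30, and
overridable), spacing is measured as a difference rather than a ratio.

Two modes exist for a new dataset: re-selecting references from its own
housekeeping candidates, or re-anchoring a known reference ID list
(`apply_reference_ids`), which re-orders the genes by their mean expression
in the new data and warns about samples whose within-sample ordering
disagrees. Re-anchoring is what makes a trained signature portable.

## Tier assignment

Within each sample the reference values are sorted ascending into boundaries
b₁ ≤ … ≤ b_n, with b₀ = 0 and b_{n+1} = ∞, and a value v receives tier
j where b_j ≤ v < b_{j+1}. Equality promotes to the higher tier — ties are
measure-zero for continuous data but common for counts, and the half-open
convention keeps reference gene r_j itself in tier j. Zero expression is
always tier 0.

## Differential expression

Per gene, tier frequencies are counted into a C × T condition-by-tier table
(row order = condition order of the metadata). Independence is tested with
the Freeman–Halton generalization of the exact test: under the null with all
margins fixed, the table probability is multivariate hypergeometric, and the
two-sided p-value sums the probabilities of all margin-fixed tables no more
probable than the observed one (probabilities compared with relative
tolerance 1e-7 to avoid floating-point tie-breaking). Zero rows/columns are
dropped first; a table left with fewer than two nonzero rows or columns
yields p = 1 with a `degenerate` flag rather than an exception, so
genome-wide runs always complete.

Two-row tables are enumerated by a vectorized column-by-column sweep with
infeasible-prefix pruning; the number of tables is first counted exactly by
polynomial DP, and enumeration is used when it is at most `mc_threshold`
(default 2×10⁶). Larger or many-row tables fall back to seeded Monte Carlo
(default 10⁵ draws): two-row nulls are sampled directly as multivariate
hypergeometric draws, many-row nulls by label permutation; the estimate is
(1 + #{prob ≤ observed})/(1 + reps). Identical tables within a run share one
p-value via a cache.

P-values are Benjamini–Hochberg adjusted (statsmodels). The Expression
Distance of a two-condition table is the difference in mean 1-based tier
index between the first and second condition; any constant index offset
cancels, |ED| ≤ n, and the sign gives the direction of regulation. Results
are ordered by FDR ascending, |ED| descending, gene ID.

Marker workflows mirror the two study designs: `pairwise_markers` merges and
deduplicates the passing genes (FDR ≤ cut, |ED| ≥ cut, optional top-k) of
every unordered condition pair; `one_vs_rest_markers` tests each class
against the pooled remainder (pooling is natural here because tiering is
per-sample and unaffected by grouping) and takes the top-k by ED (class-
elevated) or |ED|, after an optional exclusion list (e.g. non-coding RNAs —
supplied by the caller; no annotation database is consulted). The default
significance level is FDR < 0.1; ED cutoffs are dataset-specific and have no
default.

## Classification

Biomarker tiers enter the classifier as raw ordinal integers — no one-hot
encoding (which would discard ordinality) and no scaling (which would
reintroduce a dependence on the training batch and break the single-sample
contract). The classifier is an RBF-kernel SVM with C = 1 and gamma =
"scale" (recorded in the model manifest), wrapped in scikit-learn's
OneVsOneClassifier or OneVsRestClassifier for multi-class problems.
Performance is estimated by Monte Carlo cross-validation: per iteration a
stratified split holds out 10% per class (at least one sample), and the
report gives mean accuracy/precision/recall/F1 over iterations (primary)
plus the pooled confusion matrix and pooled accuracy. Samples are put in a
canonical order first so reports are invariant to input row order. Models
serialize to a zip archive holding a JSON manifest (biomarkers, references,
tier count, label order, classifier spec, format version) and the fitted
estimator; prediction validates the incoming feature schema against the
manifest.

## Benchmarking harness

`subset_benchmark` treats the full-data DEG list as gold standard and
measures precision = |full ∩ subset|/|subset| and recall =
|full ∩ subset|/|full| over repeated equal-n random subsamples per group.
`mock_fdr` splits one condition's samples into two random halves
(⌊n/2⌋/⌈n/2⌉) where any discovery is false, and reports the mock DEG count
divided by a caller-supplied reference discovery count — the DEG count each
method found in the corresponding real comparison, which ties the estimate
to the method's own discovery scale. DEG lists from external tools are
consumed as plain gene-list files, so the harness is method-agnostic.
`overlap_coefficient` is |X∩Y|/min(|X|,|Y|).

## Synthetic data

The generator emulates a two-(or multi-)condition bulk RNA-seq study at the
scale used throughout the tests: 2000 genes, 30 + 30 samples, negative-
binomial counts with dispersion 0.1 (variance = μ + 0.1μ²; a typical bulk
RNA-seq value), gene baselines log-uniform over log2 CPM 0–12, and library
sizes uniform in 8×10⁶–1.5×10⁷. Five housekeeping genes are planted at log2
CPM {2,4,6,8,10} — five references spaced ~2 log2 units apart, matching the
reference panels the method targets — with Poisson counting noise plus a 5%
lognormal wobble. With ~2000 genes these baselines make total expected
counts ≈ library size, so planted log2-CPM levels are self-consistent after
normalization. Fifty DE genes get their group-2 mean multiplied by 2^(±2)
(sign random per gene); their baselines are drawn from log2 CPM 3–9, inside
the reference-spanned range, because a fold change acting entirely below the
lowest or above the highest reference moves no tier and is invisible to the
method by construction.

A "second platform" re-expresses the same matrix through per-sample strictly
increasing transforms — log-affine a·log2(x+1)+b with a ∈ (0.5, 2),
b ∈ (0, 5), or a random increasing piecewise-linear map fixing f(0) = 0 —
and optional additive noise. Noiseless transforms are the correctness oracle
(tiers must be bit-identical); noise deliberately breaks exact tier equality
to exercise robustness reporting, and the manifest flags which regime was
generated.

What the simulation does *not* emulate: gene–gene correlation, per-gene
dispersion heterogeneity (available via an option but off by default),
outlier samples, missing genes between platforms, and non-monotone probe
effects. Passing tests therefore demonstrate the method's internal
correctness and its invariance guarantees, not its power or error control on
any particular real dataset.

## Numerical and design notes

* Exact-test tie tolerance 1e-7 (relative); enumeration vs brute-force
  rational arithmetic agrees to <1e-12 on tables with totals ≤ 30.
* The null-calibration check (no planted signal ⇒ zero discoveries at
  FDR < 0.1 in ≥ 9/10 runs) and the planted-recovery check (recall ≥ 0.8,
  precision ≥ 0.9) are run at the 2000-gene, 30-vs-30 scale above.
* Chance-level cross-validation is assessed over an ensemble of independent
  label permutations (25 permutations × 40 iterations = 1000 total),
  comparing the ensemble mean accuracy to 1/K within 3 standard errors
  across permutations. A single fixed permutation is not used as the null:
  its spurious feature–label structure is shared by every train/test split,
  so MCCV accuracy converges to a dataset-specific constant that can sit
  several iteration-SEs away from 1/K regardless of iteration count.
* Stratified MCCV splits round the per-class test size down but never below
  one sample.
* Gene IDs are matched by exact string after whitespace trimming; missing
  values are a read error (a missing value has no tier), and cross-platform
  ID mapping is the caller's responsibility.

## Known limitations

* Power is bounded by tier resolution: fold changes smaller than the
  reference spacing, or acting outside the reference range, are invisible.
* The exact test conditions on both margins and is conservative on discrete
  tables; discoveries are correspondingly cautious at small n.
* Multi-condition (C > 2) omnibus testing is supported through the generic
  R×T Monte-Carlo path only; ED is defined for two conditions.
* TMM factors are not exactly invariant to rescaling a single sample (the
  precision weights depend on depth); the effect is ~1e-3 and absorbed in
  practice by the tier discretization.
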
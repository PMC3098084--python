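# Methods

`maclust` benchmarks *class discovery* — unsupervised recovery of known
sample classes — in two-channel (cDNA) microarray experiments with a common
reference design. A complete cluster analysis is treated as a chain of
sub-processes, each with interchangeable methods:

1. normalization of the raw scans,
2. missing-value filtration and imputation,
3. gene (feature) selection,
4. optional standardization,
5. clustering of the samples,

followed by an evaluation step that scores the resulting partition against
the known classes. The meta-analysis layer runs the full factorial cross of
methods over several datasets and asks which sub-process choices matter.

## Data model

Each sample is one array hybridized against a common reference. A spot
yields foreground and background intensities in the sample (red, F635/B635)
and reference (green, F532/B532) channels. The working quantities are

- `M = log2(R/G)` — the log2 expression ratio, and
- `A = (log2 R + log2 G)/2` — the average log2 intensity,

optionally computed from background-corrected intensities `R = F635 −
B635`, `G = F532 − B532`. Flagged spots and spots with non-positive
(corrected) intensity in either channel are missing; degenerate spots never
raise, they propagate as missingness. For the background-corrected
variants, both M and A are recomputed from the corrected intensities (a
documented choice; the alternative of reusing the uncorrected A is not
offered because the two disagree only where the correction is large and the
spot is near the missingness rule anyway).

## Normalization

The dye effect is the intensity-dependent drift of M against A. It is
estimated by robust locally weighted regression (loess) of M on A and
subtracted, either fitted once per array (`norm.glob`) or once per
print-tip block (`norm.pt`); each variant exists with and without
background correction, and `no.norm` returns the raw foreground log-ratio
untouched. Loess hyperparameters are span 0.4, local linear fits, 4
robustness iterations — conventional MA-loess settings, all configurable;
`statsmodels`' lowess does the fitting, with a `delta` of 1% of the A range
to collapse near-duplicate abscissae. A fit needs at least 30 usable spots
(error otherwise, naming the array/block); if all A coincide the fit is the
constant median M.

## Filtration and imputation

Samples with ≥ 50% missing values and genes with ≥ 30% missing values are
dropped, both fractions computed on the *input* mask in a single pass
("filtered simultaneously" read literally; an iterate-to-fixed-point
variant sits behind a flag). Remaining missing cells are imputed by

- **ROW** — the gene's (row's) observed median; or
- **SVD** — iterative completion by the top-k eigengenes: missing cells
  start at 0; each round takes the SVD of the completed matrix, regresses
  every incomplete gene's observed values on the top-k right singular
  vectors restricted to observed positions, and re-estimates the missing
  cells; iteration stops when the relative Frobenius change drops below a
  tolerance. Defaults k = 10 (capped at min(dims) − 1), tol = 0.01,
  max_iter = 100; the source procedure fixes none of these, so the values
  follow the algorithm's common usage. The change history is recorded in
  the matrix provenance; hitting the cap records a warning and returns the
  last iterate. Observed cells are never modified by either method.

Duplicate spots of a gene are then averaged, and samples without a class
label are removed.

## Gene selection

Unsupervised scorers (per gene, on the imputed matrix): **STD** the sample
standard deviation (n − 1); **M** the absolute mean log2-ratio; **T1** the
moderated one-sample t statistic `|mean| / sqrt(var_mod / n)`; **PC**
replaces genes by the top-k principal-component scores of the gene-centered
matrix; **NONE** keeps everything. Supervised (positive-control) scorers:
**T2**, a Welch-style moderated two-sample t, and **Mdiff**, the absolute
between-class mean difference. Selection sizes default to N ∈ {15, 100,
1000} and k ∈ {3, 5, 15}, with STD additionally runnable at {300, 500,
1500}.

The moderated variance shrinks the gene's sample variance toward a prior:
`var_mod = (nu0*sigma0² + (n−1)*s²) / (nu0 + n − 2)`, with sigma0²
estimated as the mean sample variance of the 101 genes nearest in rank of
mean expression (window mode; a global mode and a fixed-sigma0 override
exist). `nu0 = 0` returns s² exactly, so T1/T2 reduce to the classical
one-sample and Welch t statistics — the escape hatch the tests verify
against textbook formulas. Note the general formula does not tend to s² as
nu0 → 0 (it tends to (n−1)s²/(n−2)); the exact-reduction convention at
nu0 = 0 is deliberate, so that disabling shrinkage means literal sample
variances. Defaults nu0 = 10, window = 101.

Ties in top-N selection break by ascending gene ID, making selections
nested in N and bit-reproducible. PC signs are fixed (largest-magnitude
loading positive) for the same reason; clustering itself is sign-invariant.
Standardization (z per gene across samples) applies after selection;
constant features map to zero with a warning. Standardizing PC scores is
arguably meaningless (it erases the variance ordering) but remains in the
factorial grid for design fidelity.

## Clustering

Eleven methods, all asked for ten clusters of the samples:

- six hierarchical variants — {Euclidean, Manhattan, 1 − Pearson} × {Ward,
  average linkage}, cut at ten. Ward is applied to whatever dissimilarity
  is supplied (the pragmatic convention that makes Ward meaningful on
  Manhattan/correlation input); with Euclidean input this is classical
  Ward on the observations.
- k-means, best of 100 random starts by within-cluster sum of squares
  (scikit-learn's Lloyd algorithm);
- PAM on Euclidean or correlation distance (greedy BUILD + best-improvement
  SWAP, in-package implementation);
- a one-dimensional SOM with ten units (in-package; 100 epochs, learning
  rate 0.05 → 0.01 linear, Gaussian neighborhood radius k/2 → 1 — the
  schedule is an artifact choice);
- Gaussian-mixture clustering: EM initialized from a Ward/Euclidean
  hierarchical partition, covariance family chosen between spherical and
  diagonal by BIC (full covariance is singular when features approach the
  sample count). Restricted to ≤ 500 features; the factorial grid encodes
  this as a validity predicate rather than an error.

Methods may return fewer than ten non-empty clusters (labels are compacted
to 1..c); evaluation is defined for any c ≥ 2. All stochastic methods are
reproducible from a seed.

## Evaluation: the ten-to-two optimal merge

All benchmark datasets have two true classes, but forcing two predicted
clusters punishes outliers that hive off into singletons. Emulating visual
dendrogram inspection, each method predicts *ten* clusters, which are then
exhaustively joined into two groups — all 2^(c−1) − 1 bipartitions of the c
cluster labels — choosing the bipartition that maximizes the adjusted Rand
index against the truth (ties: lexicographically smallest group-1 label
set).

Rand and adjusted Rand come from the contingency table in O(s·t): with
`a/b/c/d` the together-together / apart-apart / together-apart /
apart-together pair counts, `Rand = (a+b)/C(n,2)`, and the adjusted index
is the Hubert–Arabie permutation-model form
`(Σ C(n_ij,2) − E) / (½[Σ C(a_i,2) + Σ C(b_j,2)] − E)` with
`E = Σ C(a_i,2)·Σ C(b_j,2)/C(n,2)`. Degenerate denominators (both
partitions all-singletons or both one group) are defined as 1 for equal
partitions, else 0.

Because the merge optimizes the score, its chance level is positive. The
null distribution is simulated: 1000 random partitions (each sample
assigned uniformly and independently to one of ten labels — empty labels
allowed, the alternative of forcing non-empty labels is a flag) scored the
same way; the median and 95th percentile serve as reference lines. For a
balanced two-class truth of 100 samples the null median is ≈ 0.05 and the
95th percentile ≈ 0.11 (recomputed by `scripts/acceptance.py`).

## Meta-analysis

The unsupervised grid is 5 normalizations × 2 imputations × 2
standardizations × 13 selections × 11 clusterings minus the invalid
mixture-model cells = **2780** analyses per dataset (the supervised
selections add 1280; the survivor subset spans 288; seven cohorts give
19460 runs). The runner caches the (normalization, imputation) stage and
the selection stage, derives per-run seeds from a master seed (CRC32 of the
run coordinates, < 2³¹), and records failures as rows with a reason instead
of aborting.

**Variance decomposition.** A linear model of aRand on the categorical
factors (dataset, normalization, standardization, imputation, selection,
clustering) plus all pairwise interactions, with sequential (Type I) sums
of squares in that canonical order (order is configurable and logged —
Type I is order-dependent). The SS are computed by incremental least
squares: each term's SS is the residual-SS drop when its indicator block
enters, its df the rank increase. This handles the structurally missing
mclust cells exactly (inestimable cells contribute no rank) where a
textbook ANOVA call would fail; on balanced designs it agrees with
`statsmodels.anova_lm(typ=1)` to 1e-8 (tested). Terms are flagged at
p < 0.001.

**Elimination.** Within each of {normalization, gene selection, clustering},
every unordered pair of surviving methods is compared by a two-sided
Wilcoxon signed-rank test on aRand values paired on (dataset + all other
sub-process settings), using only settings where both methods have a score
(the mixture-model validity asymmetry forces this restriction). P-values
are Bonferroni-multiplied by the number of tests in the current iteration
(a cumulative-count variant is a flag); if the minimum corrected p falls
below 0.001, the pair's lower-paired-median method is removed with all its
analyses, and the procedure repeats until no removal occurs. "Lower paired
median" as the loser criterion is the package's choice — it matches the
rank-based test. The trace mirrors a removal table: removed method,
corrected p, superior method. The counts of possible comparisons are
C(13,2) = 78 selections, C(11,2) = 55 clusterings, C(5,2) = 10
normalizations.

## Synthetic data

The generator produces the only inputs the test-suite needs. Per gene: a
log-normal reference intensity (log2 ~ N(9, 1.5)) and a baseline log-ratio
m0 ~ N(0, 0.3) shared by both classes. A chosen subset of genes gets a
class-dependent shift of ±de_effect/2 with random sign, so the expected
between-class difference in true M is exactly `de_effect`. Per spot, the
red channel is multiplied by 2^(dye bias + block offset): the dye bias is
`amp·[sin(2π·(A−Amin)/range) + 0.3·(2·(A−Amin)/range − 1)]` — a curved,
loess-removable MA pattern — and block offsets are N(0, block_offset_sd)
per print-tip block and array. Additive gamma background (mean
`background_mean`) enters both channels; the written background columns are
that background times U(0.9, 1.1), so correction recovers the signal up to
estimation noise and occasionally drives weak spots negative (exercising
the below-background missingness rule). Flags are Bernoulli(flag_rate);
MCAR dropouts are written as zero foreground. A fraction of genes is
printed twice to exercise duplicate collapsing. Configs whose expected
missing fraction (MCAR plus flags) reaches 0.5 are rejected up front, since
sample filtration would then remove everything.

Defaults — 60 samples in two balanced classes, 2000 genes, 200 DE genes at
1.5 log2 units, dye-bias amplitude 0.5, 16 blocks with offset SD 0.2, spot
noise SD 0.4, 2% flags, 2% dropouts, 5% duplicates — are sized like a
mid-range cohort of the kind the benchmark targets (tens of samples,
thousands of spots) while keeping a full 288-spec grid over three cohorts
inside a coffee break on one CPU.

What the generator does **not** emulate: biological covariance between
genes (genes are independent given the class), spatial artifacts beyond
per-block offsets, intensity-dependent variance, and one-channel
platforms. Passing tests therefore demonstrate that the machinery is
correct and that planted structure of a stated size is recovered — not that
any particular method ranking carries over to real cohorts, where the
original analyses found the dataset itself to be the dominant factor.

## Numerical and degenerate-input choices

- Loess on < 30 spots errors naming the block; all-equal A gives a constant
  (median) fit.
- log2 of non-positive intensity never raises: the spot becomes missing.
- Constant genes: STD/M/T1 scores are 0 (t statistics with zero numerator
  and denominator are defined as 0); standardization maps constant features
  to zero with a warning; correlation distance on a constant sample errors
  naming the sample.
- Partitions are relabelled 1..c by first appearance everywhere, so
  label-dependent code paths are deterministic.
- All RNG flows through `numpy.random.default_rng` seeds; derived seeds use
  CRC32 and stay below 2³¹.

## Problem sizes used by the test suite and acceptance script

Unit tests run on 24-sample × 400-gene experiments; the end-to-end checks
use three 60 × 2000 cohorts under the 288-spec survivor grid, a 10-seed
supervised-recovery study at 60 × 2000, 1000-replicate nulls at n = 40 and
100, and 10,000 fuzzed instances (n ≤ 50) for the partition-metric oracle
equivalence. These sizes were chosen so the whole suite completes in a few
minutes on a single CPU while every stage still sees realistic shapes.

## Known limitations

- The Hartigan–Wong k-means variant is not available in the scientific
  Python stack; Lloyd iterations with 100 restarts stand in. The
  best-of-restarts property, which is what the benchmark exercises, holds
  either way.
- Ward on non-Euclidean dissimilarities is a convention, not a theorem;
  results for `hclust.manh.ward` / `hclust.corr.ward` depend on it (any
  implementation combining Ward with such distances makes an equivalent
  choice).
- The SOM training schedule and the mixture-model covariance families are
  artifact choices where the underlying methods have free parameters.
- Sequential ANOVA percentages depend on term order; the canonical order is
  documented above and configurable.
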
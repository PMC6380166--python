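# Methods

## Screening statistic and thresholds

The genome-wide screen summarises each gene's FPKM row by the
coefficient of variation CV% = 100·SD/mean. The SD is the *sample* SD
(n−1 denominator): the convention of the qPCR stability literature, and
the one that reproduces the packaged qPCR panel's printed CV column
from its mean/SD pairs. All thresholds are strict inequalities, mirroring
their verbal definitions: the constitutive filter keeps genes with
FPKM *greater than* the floor (default 1) in every sample, and
shortlists keep CV *lower than* the threshold (defaults 20% and 16%).
CV is carried at full precision internally and rounded only when
written. Shortlist ties in CV are broken lexicographically by gene id
so output order is reproducible.

## The four stability statistics

All four operate on the quantification cycle Cq, which is linear in
−log(expression); "stability" is always a dispersion, so lower is more
stable, every statistic is non-negative, and all four are zero in the
all-constant-rows limit.

**geNorm.** Input is the relative quantity Q = E^(minCq − Cq) with each
gene's measured efficiency E (default 2.0), the transform defined by
the original geNorm program; each gene's row maximum is exactly 1. For
genes j,k the pairwise variation V_jk is the sample SD over samples of
log₂(Q_j/Q_k); M_j is the mean of V_jk over k ≠ j. The gene with the
largest M is removed and M recomputed until two genes remain. A gene's
reported M is its value in the round of its elimination; the final two
genes keep their M from the last round with ≥3 genes active (a 2-gene
M is a degenerate single pairwise SD) and share the averaged rank 1.5,
since geNorm cannot order the final pair. Elimination ties are broken
by removing the lexicographically later gene id. The pairwise
variation V(n,n+1) is the sample SD of log₂(NF_n/NF_{n+1}), with NF_n
the per-sample geometric mean of the n most stable genes' quantities.

**NormFinder (ungrouped).** Each sample's panel mean Cq is subtracted;
a gene's stability is the sample SD of the residual. This is the
ungrouped variant: no condition labels enter, matching how the
aggregation treats all samples of a subset as one pool. The original
inter/intra-group decomposition is intentionally out of scope.

**BestKeeper.** Descriptive dispersion of raw Cq: the reported "SD" is
the mean absolute deviation from the *geometric* mean of the gene's Cq,
CV% = 100·SD/geometric mean, plus min/max and the Pearson correlation
(two-sided p) of the gene against the BestKeeper index, the per-sample
geometric mean over all candidate genes. Ranking uses the SD — the
program's own stability criterion — and genes with SD > 1 cycle carry
an `unstable` flag. BestKeeper is the only statistic not invariant to
per-gene additive Cq shifts (multiplicative expression rescaling); the
suite documents and tests this asymmetry rather than "fixing" it.

**Comparative ΔCt.** For each gene, the mean over all other genes of
the sample SD of the per-sample Cq difference. On a common efficiency
scale this is algebraically the first-round geNorm M (up to the log₂ E
factor), which the test suite asserts as a rank correlation property.

**Comprehensive ranking.** Each method contributes its rank vector
(average ranks at ties); the comprehensive score is the geometric mean
of the four ranks, so it depends only on orderings and is invariant to
monotone transforms of any method's raw values. Scores are ranked with
average ties. Stress subsets re-run the entire suite on the column
subset: temperature {C, HT, LT}, salinity {C, HS, LS}, combined = all.

Missing Cq cells are a hard error throughout — silent imputation would
distort every SD-based statistic. Stability values are reported to 3
decimals at the I/O layer; ranking is computed at full precision.

## Quantification

Efficiency comes from an OLS fit of Cq on log₁₀ template input over a
10-fold dilution series: E = 10^(−1/slope), with slope −3.3219
corresponding to perfect doubling. A non-negative slope marks the curve
invalid rather than producing E ≤ 1 silently.

ΔΔCq uses time-matched controls: the control animals were sampled at
the same 1/24/48 h time points, so each treated cell is compared to the
control cell of its own time point. The fold-change base defaults to 2
(the classic 2^(−ΔΔCq)); an efficiency-corrected mode applies the
target's and reference's measured efficiencies separately
(E_t^(−ΔCq_t)/E_r^(−ΔCq_r)). Control cells are reported as ΔΔCq 0 and
fold 1 by definition. Per-cell significance is a two-sided Welch t-test
on the ΔCq replicates (n = 3 per cell; variance homogeneity cannot be
verified at that size, so the unequal-variance test is the default). No
multiple-testing correction is applied across the 12 treatment × time
cells by default, matching per-cell reporting practice; the
normalizer-comparison table instead surfaces the practically relevant
error — cells where switching the reference gene changes the called
direction or significance.

## Architecture trends

Genes are sorted by the grouping key (CV or mean expression) descending
and split into G contiguous groups (default 42); with n = qG + r genes
the first r groups take q+1. Group pairs are compared per structure
variable with the Mann–Whitney U test: exact enumeration when
min(n) ≤ 8 without ties, otherwise the tie-corrected normal
approximation with continuity correction (at the default group sizes
of ~200 the approximation is essentially exact). These branches are
delegated to `scipy.stats.mannwhitneyu`, which implements precisely
this rule. The trend summary flags a variable when group 1 (largest key
values) differs from every other group with a consistent median
direction and at least half of those comparisons significant — the
pattern expected when highly expressed genes are systematically more
compact. Pairwise p-values are reported uncorrected (exploratory use);
a Benjamini–Hochberg pass can be applied downstream if desired.
Structure rows with missing fields are dropped with a logged count, and
`cds_length ≤ transcript_length ≤ gene_length` violations are flagged
in a boolean column rather than rejected, tolerating annotation quirks.

The cross-platform concordance statistic (Pearson r between the panel's
mean FPKM and mean Cq) uses **raw** FPKM: on the packaged 14-gene panel
the raw convention gives r = −0.637 whereas log₁₀-FPKM gives −0.708,
so the raw-scale convention is pinned here and used by the acceptance
script.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study's sampling design (5 treatments × 3
times × 3 replicates) and its observable statistics: FPKM in the
realistic 2.6–15 500 mean range, per-gene CV from a few percent to
several hundred percent, Cq in the 16–25 band via intercept 35 (the Cq
of one relative expression unit), and efficiencies around 1.94–2.07.
Biological noise is log-normal with σ = √ln(1+CV²), which targets the
coefficient of variation exactly and keeps values positive; treatment
effects are multiplicative per (treatment, time) cell; Cq noise is
additive Gaussian per well, the standard qPCR error model. Random
streams are split per gene from the master seed, so extending a panel
never changes existing genes' draws, and identical seeds give
bit-identical matrices.

The default 14-gene scenario — 3 stable genes at CV 3%, 8 responsive
genes with 2–4-fold effects in specific cells, 3 noisy genes at CV 50%,
simulated with Cq noise SD 0.1 cycles — is the fixed reference
condition for parameter-recovery tests. Within-treatment biological
variance is not reported for the real data, so these levels were chosen
once as plausible for bulk RNA-Seq of pooled pharynx tissue and qPCR
triplicates; they are deliberately not tuned per test.

What the generator does **not** model: read-level sampling (FPKM is
drawn directly, not computed from counts), gene–gene correlation,
batch/plate effects, amplification inhibition or primer-dimer
artifacts, and heteroskedastic Cq noise at low template. Passing
recovery tests therefore demonstrates that the statistics identify the
designed stability structure under idealised independent noise — not
that any particular gene is stable in real tissue.

The ΔΔCq recovery condition (true 4-fold induction, stable reference,
Cq noise SD 0.15) is summarised by the across-seed mean of the
per-dataset fold estimates over 100 simulated datasets; individual
3-replicate datasets scatter around the truth with a slight upward
Jensen bias inherent to averaging 2^(−ΔΔCq) over replicates.

## Problem sizes and numerical conventions

Recovery simulations use 100 datasets of 14 genes × 45 samples (the
full study geometry), which the four-method suite processes in a few
seconds; oracle-equivalence checks use 50 random 5-gene × 10-sample
matrices compared to brute-force reimplementations at 1e-9. Sample SDs
use the n−1 denominator everywhere. Pearson and Welch statistics come
from scipy; OLS from `scipy.stats.linregress`. Exactly-tied geNorm M
values at elimination are resolved by gene id (later id removed first)
so results are permutation-safe, and all rank ties elsewhere use
average ranks.

## Known limitations

* NormFinder is the ungrouped variant; grouped inter/intra-group bias
  decomposition is not implemented.
* The comprehensive ranking reproduces the geometric-mean-of-ranks
  aggregation scheme, not any particular web tool's unpublished
  internal conventions; orderings on real panels should be read
  qualitatively.
* Multi-gene normalization factors (geometric mean of several
  references as a single normalizer) are limited to geNorm's V
  statistic; ΔΔCq supports one reference at a time, compared side by
  side.
* The structure-table generator draws architecture variables from
  simple parametric families; it is meant for testing trend detection,
  not for simulating realistic genome annotation.
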
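# Methods

## Recurrence model

A cohort is a gene × sample matrix of gene-level copy number on the
log2(CN/2) scale, diploid = 0. Amplification is a binary event: value
strictly greater than a threshold `t` (default 0.3). The strict inequality
matters only for values exactly at the threshold, but it is part of the
calling contract and is boundary-tested.

For the recurrence test, let `A` be the binary call matrix and
`p_i = (1/G) Σ_g A[g, i]` sample `i`'s genome-wide amplification rate.
Under the null hypothesis that gene `g` is amplified in sample `i`
independently with probability `p_i` (burden only, no gene-specific
selection), the amplified-sample count `k_g` follows a Poisson binomial
distribution with parameters `(p_1, …, p_n)`. The reported p-value is the
inclusive upper tail `P(X ≥ k_g)` — inclusive being the conservative
convention for discrete tests — and q-values come from Benjamini–Hochberg
over all genes. Records are sorted by (q, p, gene) for determinism.

Modelling choices worth making explicit:

* **The tested gene is not excluded from the rate estimate.** With
  genome-scale gene counts the induced bias is O(1/G); at G = 500 it is
  already negligible in simulation (null calibration holds).
* **Independence across samples and genes** is assumed by the null. Real
  tumours violate this through arm-level events that amplify whole blocks
  of genes together; the per-sample rate absorbs the sample-level part of
  that dependence but not the gene–gene part, so neighbouring genes share
  p-values in practice. The test is a per-gene screen, not a peak caller.
* **Deletions are ignored.** The test concerns amplification recurrence
  only; values below −0.3 simply call 0.
* **Missing copy-number values call 0** (not-amplified) rather than dropping
  the sample, keeping the matrix rectangular; per-gene missing counts are
  reported on the call object so heavily missing genes can be filtered by
  the caller.

### Poisson binomial computation

The pmf is computed by exact O(n²) dynamic-programming convolution of the
n Bernoulli distributions for n ≤ 5000. Above that, a characteristic-
function route evaluates the pmf via the discrete Fourier transform (with
products accumulated as complex log-sums); the two agree to < 1e-9 on
overlap sizes, which the test suite checks. Tail probabilities are obtained
by summation from the top of the support in double precision, which keeps
relative error small for tiny tails; at this pipeline's scales (rates
≥ 0.05, n ≤ a few thousand) attainable tails sit far above double-precision
underflow, so no log-space representation is carried. One pmf serves all
genes of a cohort, because the parameter vector is shared — this is what
makes 50-replicate simulation studies cheap.

## Survival analysis

Kaplan–Meier estimation uses the standard product-limit form with
censored-at-event-time patients counted at risk. The two-group log-rank
test accumulates observed-minus-expected events over pooled distinct event
times with the hypergeometric variance and refers the statistic to χ²(1).
Both are implemented directly in numpy (the cutpoint scan below calls the
log-rank test hundreds of times per table, and tens of thousands of times
across simulation studies, so per-call overhead matters); the test suite
cross-checks the statistic and p-value against lifelines to machine
precision on random tables.

**Minimum-p-value dichotomization.** Candidate cutpoints are the midpoints
between consecutive distinct marker values for which both groups retain at
least `min_group_frac` (default 10 %) of the patients — the maximally
selected rank statistic convention. Ties at the cutpoint go to the low
group ("≤ low / > high"). Ties at the minimum p are broken toward the more
balanced split, then toward the lower cutpoint, so output is deterministic.
The selected p is **not corrected** for the multiplicity of candidate
cutpoints, matching common practice in biomarker survival reports; the
resulting anti-conservatism is real (null rejection at 5 % runs around
40–45 % in the simulation study) and is asserted by the test suite and
flagged via `multiple_testing_corrected=False` on the result rather than
silently corrected away.

## CRISPR essentiality

Gene-effect scores follow the screen normalisation convention: median 0 for
non-essential genes, −1 for known common essentials, more negative = more
depleting. "Top 10th percentile of most depleting genes" is operationalised
as percentile rank ≤ `top_frac` within each line, ranks ascending from the
most negative score with average ranks for ties; a gene is common-essential
when that holds in at least `line_frac` of the lines scoring it (non-strict
≥, pairwise deletion of missing scores). Being rank-based, the call set is
invariant under any strictly increasing per-line transform of scores — a
property test. Dependent-line fractions use strictly greater-than on the
dependency probability threshold (default 0.5). Co-dependency scans compute
Pearson r of every gene's effect profile against a query gene with pairwise
deletion, t-distribution p-values and BH q-values across testable genes.

## Drug association

AUC values are clipped into [0, 1] (curve re-fitting is upstream of this
package; the clip count is reported). The median split assigns lines
strictly above the median to "high", ties to "low". Group comparison is the
Mann–Whitney U test on AUC (direction read off the group medians);
correlation is Pearson over the intersecting lines, with an optional
boolean per-line subset (e.g. restricting to mutation wild-type lines)
applied first and the effective n always reported.

## Integration

Each cancer type receives four boolean flags — upregulated (tumour-vs-
normal q < α with tumour median higher), prognostic (min-p split p < α with
the high group worse), CN-correlated (r ≥ `r_min`), amplified (amplified
fraction ≥ `f_min`) — and the 16-cell combination table is emitted; counts
sum to the number of evaluable types, and types with missing statistics are
listed as not evaluable. Defaults α = 0.05, `r_min` = 0.6 (the lower edge
of the per-type CN–expression correlations this flag is meant to capture),
`f_min` = 0.1; all thresholds are parameters surfaced in the output
metadata, never constants.

## Statistical kernel conventions

* **Mann–Whitney U**: exact enumeration p-value when both groups have ≤ 8
  observations and the pooled data is tie-free; otherwise the normal
  approximation with tie and continuity corrections (delegated to scipy
  under this boundary rule). Fully tied data returns p = 1 by convention so
  parameter sweeps never crash on degenerate draws.
* **Pearson**: requires n ≥ 3 and nonzero variance; constant input raises a
  dedicated error rather than returning NaN.
* **BH**: applied to raw p-values (step-up, capped at 1, mapped back to
  input order) via statsmodels.

## Synthetic data generators

The generators produce inputs with the statistical structure the analysis
assumes — and only that structure.

* `simulate_cna`: per-sample background rates uniform on [0.05, 0.2]
  (default), a burden range typical of moderately unstable tumour cohorts;
  seeded genes get +0.4 excess probability, a strong recurrent-gain signal.
  Amplified cells draw log2 ratios as 0.3 + |N(0.3, σ)|, non-amplified
  cells N(0, σ) truncated at 0.3, so true labels and threshold calls
  coincide exactly at default noise; with larger σ the label/call
  discordance is intentional and measurable. Not emulated: segment
  structure (each cell is independent), purity/ploidy effects, deletions.
* `simulate_expression`: baseline 0 + coupling × log2 ratio + N(0, σ_e),
  defaults coupling 1.0, σ_e 0.5, giving per-gene CN–expression r around
  0.5–0.6 for seeded genes — the closed form is
  r = c·σ_cn/√(c²σ_cn² + σ_e²), which the tests use as an oracle. The
  `expr_noise_sd` field exists precisely because that closed form needs a
  noise scale. No count-level (RNA-seq) noise model.
* `simulate_survival`: exponential event times with hazard
  h₀·exp(β·marker), h₀ = 0.1, β = 1.0 default; independent uniform
  censoring on (0, T_max) with T_max found by geometric bisection so the
  expected censored fraction hits the target ± 0.02 — simpler than
  inverse-probability schemes and adequate for testing. No competing risks,
  no covariates beyond the single marker.
* `simulate_screen`: essential genes N(−1, 0.1), non-essential N(0, 0.1)
  per line; dependency probability is a logistic in the negated score
  through (score −1 ↦ 0.9, score 0 ↦ 0.1). Real screens have off-target
  structure, copy-number artefacts and batch effects that this ignores.
* `simulate_drug_response`: AUC = clip(0.5 + slope·standardised expression
  + N(0, σ), 0, 1); positive slope emulates a resistance association,
  negative a sensitising one; asymptotic r = s/√(s² + σ²).

All generators are pure functions of (spec, seed); sub-streams are derived
from the single seed with fixed offsets, so adding a generator never
perturbs existing draws. Passing tests on these inputs demonstrates the
statistical machinery (calibration, recovery, invariances), not robustness
to the artefacts of real consortium data (normalisation batch effects,
segment-level correlation, informative censoring).

## Problem sizes

The simulation studies run at 500 genes × 200 samples with 50 replicate
cohorts for recovery and 20 for null calibration; survival studies at
n = 300 (recovery, 50 replicates) and n = 100 (null, 200 replicates);
screens at 1000 genes × 100 lines; drug association at n = 2000 for
asymptotics and n = 25–40 for small-sample sign recovery. These sizes give
tight Monte-Carlo error on every asserted rate while keeping the whole
battery fast on a single CPU.

## Known limitations

* The recurrence test is gene-level; it does not deconvolve focal vs
  arm-level events or identify peak boundaries.
* The minimum-p cutpoint is reported with its uncorrected p; downstream
  users wanting honest type-I error must validate the cutpoint externally.
* The log-rank implementation handles exactly two groups; stratified or
  trend variants are out of scope.
* Which copy-number value column (focal vs total) feeds the caller is the
  caller's choice; the package applies whatever matrix it is given.
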
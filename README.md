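# panamp

Pan-cancer copy-number amplification recurrence analysis and its downstream
companions: survival cutpoint selection, CRISPR essentiality calling, and
drug-response association.

## The problem

In tumour genomes, some genes are amplified in many samples simply because
those samples carry a high genome-wide amplification burden; other genes are
amplified recurrently because the gain is positively selected. Telling the
two apart needs a null model that conditions on each sample's own burden.

`panamp` implements that test. Given a gene × sample matrix of gene-level
copy number on the log2(CN/2) scale (diploid = 0):

1. **Amplification calling** — a cell is amplified iff its value is
   *strictly* greater than a threshold (default 0.3, ≈ 2.46 copies).
2. **Sample rates** — each sample's rate `p_i` = fraction of genes amplified
   in that sample.
3. **Recurrence test** — for a gene amplified in `k` of `n` samples, the
   p-value is the inclusive upper tail of the Poisson binomial distribution,

   `p = P(X ≥ k)`, `X = Σ_i Bernoulli(p_i)`,

   computed by exact dynamic-programming convolution (a
   characteristic-function DFT route takes over for very large cohorts).
   Gene-level p-values are converted to q-values by Benjamini–Hochberg.

Around this core the package provides the associated biomarker analyses:
Kaplan–Meier curves and the two-group log-rank test; dichotomization of a
continuous marker by the **minimum-p-value approach** (scan every feasible
cutpoint, keep the log-rank-minimising one — reported uncorrected and
therefore anti-conservative, which the test suite demonstrates); a
**common-essential** caller for CRISPR screens (a gene ranking in the top
10th percentile of depletion in ≥ 90 % of cell lines) plus dependent-line
fractions (dependency probability strictly > 0.5) and co-dependency
correlation scans; and expression/AUC drug-sensitivity association (median
split + Mann–Whitney, Pearson correlation, optional mutation-status
subsets). A criteria-integration step intersects the per-cancer-type flags
(upregulated, prognostic, CN–expression-correlated, amplified).

A fully deterministic synthetic-data generator produces every input the
pipeline consumes, with known ground truth, so the whole analysis is
testable without any external download.

## Worked example

```python
from panamp import (CohortSpec, call_amplification, min_p_split,
                    recurrence_test, sample_rates, simulate_cna,
                    simulate_expression, simulate_survival)

spec = CohortSpec(n_genes=500, n_samples=200, seeded_genes=(0, 1, 2, 3, 4), seed=7)
cn, labels = simulate_cna(spec)          # log2(CN/2) matrix + ground truth
amp = call_amplification(cn)             # strict > 0.3
rec = recurrence_test(amp)
print(rec.head(6).to_string(index=False))
```

```
 gene   k  frequency      p_value      q_value
G0002 109      0.545 1.610442e-45 8.052211e-43
G0001 102      0.510 3.490999e-39 8.727497e-37
G0003 100      0.500 1.871328e-37 3.118880e-35
G0004  99      0.495 1.328204e-36 1.660255e-34
G0000  98      0.490 9.234019e-36 9.234019e-34
G0080  39      0.195 5.447234e-03 4.539361e-01
```

The five seeded genes (amplified in ~50 % of samples against a background
burden averaging 13 %) dominate the ranking with vanishing q-values; the best
unseeded gene stays far from significance (q ≈ 0.45), so exactly 5 genes pass
q < 0.05. Continuing with survival:

```python
expr = simulate_expression(cn, spec)
surv = simulate_survival(expr.loc["G0000"].to_numpy(), spec)
res = min_p_split(surv)
print(res.cutpoint, res.p_value, res.n_low, res.n_high)
# 0.222  3.81e-06  93 107
```

With a positive log hazard ratio per expression unit, the scan finds a
near-median cutpoint splitting 93 vs 107 patients at log-rank p ≈ 4e-06; the
full `(cutpoint, p)` scan trace is kept on the result for auditing.

The same pipeline is available as a CLI (`panamp simulate`, `call-amp`,
`recurrence`, `survival`, `essentials`, `drug-assoc`, `integrate`); all
thresholds live in a JSON `RunConfig`, and every subcommand is reproducible
bit-for-bit for a fixed seed.

## Further reading

`docs/methods.md` documents the statistical model, every tunable parameter
with its default and rationale, what the synthetic generators do and do not
emulate, and known limitations.
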
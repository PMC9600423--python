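"""Amplification calling and Poisson-binomial recurrence testing.

The pipeline: threshold a gene x sample log2(CN/2) matrix into binary
amplification calls, estimate each sample's genome-wide amplification rate,
and test each gene's amplified-sample count against the Poisson binomial
null parameterised by those rates.  A gene whose count is improbable under
per-sample burdens alone is recurrently amplified beyond chance.  Gains only
are considered; deletions (log2 ratio < -0.3) play no role here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from panamp.core_stats import bh_adjust, mann_whitney, pearson, poibin_upper_tail_all

__all__ = [
    "AmplificationMatrix",
    "GroupCompareResult",
    "call_amplification",
    "cn_expression_summary",
    "frequency_track",
    "group_expression_compare",
    "recurrence_test",
    "sample_rates",
]

#: default log2(CN/2) amplification threshold (strict >)
DEFAULT_THRESHOLD = 0.3


@dataclass(frozen=True)
class AmplificationMatrix:
    """Binary amplification profile derived from a copy-number matrix.

    ``calls`` is a genes x samples {0,1} integer DataFrame; ``n_missing``
    reports, per gene, how many cells were missing in the source matrix and
    therefore called 0.
    """

    calls: pd.DataFrame
    threshold: float
    n_missing: pd.Series

    @property
    def genes(self) -> pd.Index:
        return self.calls.index

    @property
    def samples(self) -> pd.Index:
        return self.calls.columns


class GroupCompareResult(NamedTuple):
    statistic: float
    p_value: float
    median_a: float
    median_b: float


def call_amplification(
    cn: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> AmplificationMatrix:
    """Threshold a log2(CN/2) matrix into binary amplification calls.

    A cell is amplified iff its value is strictly greater than ``threshold``
    (0.3 by default, i.e. more than ~2.46 copies in a diploid genome).
    Missing values call 0 so the matrix stays rectangular; per-gene missing
    counts are carried on the result.
    """
    if cn.size == 0:
        raise ValueError("copy-number matrix is empty")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if cn.index.has_duplicates or cn.columns.has_duplicates:
        raise ValueError("gene and sample identifiers must be unique")
    values = cn.to_numpy(dtype=float)
    calls = pd.DataFrame(
        (values > threshold).astype(np.int8), index=cn.index, columns=cn.columns
    )
    n_missing = cn.isna().sum(axis=1)
    return AmplificationMatrix(calls=calls, threshold=float(threshold), n_missing=n_missing)


def sample_rates(amp: AmplificationMatrix) -> pd.Series:
    """Per-sample amplification rate p_i = amplified genes / total genes."""
    if amp.calls.shape[0] == 0:
        raise ValueError("amplification matrix has no genes")
    return amp.calls.mean(axis=0)


def recurrence_test(amp: AmplificationMatrix) -> pd.DataFrame:
    """Per-gene Poisson binomial recurrence test with BH q-values.

    For gene g amplified in ``k_g`` of n samples, the p-value is the
    inclusive upper tail ``P(X >= k_g)`` of the Poisson binomial
    distribution with the per-sample rates as success probabilities.  The
    tested gene is not excluded from the rate estimate; with genome-scale
    gene counts the induced bias is O(1/n_genes).

    Returns a DataFrame with columns ``gene, k, frequency, p_value,
    q_value`` sorted by (q, p, gene).
    """
    n_genes, n_samples = amp.calls.shape
    if n_samples < 2:
        raise ValueError("recurrence test needs at least 2 samples")
    rates = sample_rates(amp).to_numpy()
    tail = poibin_upper_tail_all(rates)  # one pmf serves every gene
    k = amp.calls.sum(axis=1).to_numpy()
    pvals = tail[k]
    qvals = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "gene": amp.genes,
            "k": k,
            "frequency": k / n_samples,
            "p_value": pvals,
            "q_value": qvals,
        }
    )
    out = out.sort_values(["q_value", "p_value", "gene"], kind="mergesort")
    return out.reset_index(drop=True)


def _chrom_key(chrom: str) -> tuple[int, int | str]:
    """Natural chromosome order: numeric first, then X/Y/others lexically."""
    c = str(chrom)
    c = c[3:] if c.lower().startswith("chr") else c
    return (0, int(c)) if c.isdigit() else (1, c)


def frequency_track(
    amp: AmplificationMatrix, positions: pd.DataFrame
) -> pd.DataFrame:
    """Genome-ordered per-gene amplification frequency with recurrence q-values.

    ``positions`` must carry columns ``gene, chrom, start, end`` (0-based,
    half-open) and may carry ``cytoband``.  Genes without a position are
    reported in a warning and excluded.  Output is ordered by
    (chromosome, start) and suitable for plotting an amplification-frequency
    track along the genome.
    """
    if positions is None or len(positions) == 0:
        raise ValueError("position table is empty")
    required = {"gene", "chrom", "start", "end"}
    if not required.issubset(positions.columns):
        raise ValueError(f"position table must have columns {sorted(required)}")
    records = recurrence_test(amp)
    merged = records.merge(positions, on="gene", how="left")
    missing = merged.loc[merged["chrom"].isna(), "gene"].tolist()
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) without positions excluded from the track: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}",
            stacklevel=2,
        )
        merged = merged.dropna(subset=["chrom"])
    merged = merged.assign(_ckey=merged["chrom"].map(_chrom_key))
    merged = merged.sort_values(["_ckey", "start"], kind="mergesort").drop(columns="_ckey")
    cols = ["chrom", "start", "end", "gene", "frequency", "q_value"]
    if "cytoband" in merged.columns:
        cols.append("cytoband")
    return merged[cols].reset_index(drop=True)


def cn_expression_summary(
    cn: pd.DataFrame,
    expr: pd.DataFrame,
    gene: str,
    group_labels: pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Per-group copy-number/expression correlation and amplified fraction.

    For one gene and a per-sample grouping (e.g. cancer type), computes the
    Pearson correlation between that gene's copy number and expression
    within each group, together with the fraction of samples called
    amplified.  Groups with fewer than 3 samples or a constant vector get
    NaN correlations.
    """
    if gene not in cn.index or gene not in expr.index:
        raise KeyError(f"gene {gene!r} absent from copy-number or expression matrix")
    common = cn.columns.intersection(expr.columns).intersection(group_labels.index)
    if len(common) == 0:
        raise ValueError("no samples shared by copy-number, expression and labels")
    x = cn.loc[gene, common].astype(float)
    y = expr.loc[gene, common].astype(float)
    rows = []
    for grp, samples in group_labels.loc[common].groupby(group_labels.loc[common]).groups.items():
        xs, ys = x.loc[samples], y.loc[samples]
        ok = xs.notna() & ys.notna()
        xs, ys = xs[ok], ys[ok]
        r = p = np.nan
        if len(xs) >= 3 and xs.nunique() > 1 and ys.nunique() > 1:
            r, p = pearson(xs, ys)
        prop = float((xs > threshold).mean()) if len(xs) else np.nan
        rows.append({"group": grp, "r": r, "p_value": p, "prop_amplified": prop, "n": len(xs)})
    return pd.DataFrame(rows)


def group_expression_compare(
    expr_tumor: Sequence[float], expr_normal: Sequence[float]
) -> GroupCompareResult:
    """Tumour-vs-normal expression comparison by the Mann–Whitney U test."""
    u, p = mann_whitney(expr_tumor, expr_normal)
    return GroupCompareResult(
        statistic=u,
        p_value=p,
        median_a=float(np.median(np.asarray(expr_tumor, dtype=float))),
        median_b=float(np.median(np.asarray(expr_normal, dtype=float))),
    )
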
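"""Essentiality calling and co-dependency analysis from CRISPR screens.

Gene-effect scores follow the pan-cancer screen convention: more negative
means stronger depletion on knockout, with non-essential genes normalised
to a median of 0 and known common essentials to -1.  A *common essential*
gene ranks in the top 10th percentile of depletion in at least 90% of the
screened cell lines — a rank-based rule, hence invariant to any strictly
increasing per-line rescaling of scores.  A line is *dependent* on a gene
when its dependency probability strictly exceeds 0.5.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from panamp.core_stats import UndefinedCorrelationError, bh_adjust

__all__ = [
    "DependentFraction",
    "call_common_essentials",
    "codependency_scan",
    "dependent_fraction",
    "rank_profile",
]


class DependentFraction(NamedTuple):
    n_dependent: int
    n_total: int
    fraction: float


def rank_profile(effects: pd.DataFrame) -> pd.DataFrame:
    """Per-line percentile rank of each gene's depletion score.

    Within each cell line, genes are ranked ascending by score (the most
    negative, most depleting gene gets rank 1) with average ranks for ties;
    the percentile is rank / number of scored genes in that line.  Missing
    scores stay missing and do not enter the line's denominator.
    """
    if effects.shape[0] < 2:
        raise ValueError("need at least 2 genes for meaningful percentiles")
    if effects.index.has_duplicates or effects.columns.has_duplicates:
        raise ValueError("gene and line identifiers must be unique")
    values = effects.to_numpy(dtype=float)
    ranks = stats.rankdata(values, method="average", axis=0, nan_policy="omit")
    n_scored = np.sum(~np.isnan(values), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = ranks / n_scored
    return pd.DataFrame(pct, index=effects.index, columns=effects.columns)


def call_common_essentials(
    effects: pd.DataFrame, top_frac: float = 0.10, line_frac: float = 0.90
) -> pd.DataFrame:
    """Flag genes depleting in the top ``top_frac`` of genes in >= ``line_frac`` of lines.

    Returns one row per gene: ``gene``, ``fraction_top`` (fraction of lines
    in which the gene falls in the top percentile band, over lines where the
    gene was scored), and ``is_common_essential``.
    """
    for name, v in (("top_frac", top_frac), ("line_frac", line_frac)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1]")
    pct = rank_profile(effects)
    in_top = pct.le(top_frac)
    scored = pct.notna().sum(axis=1)
    if (scored == 0).any():
        raise ValueError("some genes have no scored lines")
    fraction = in_top.sum(axis=1) / scored
    return pd.DataFrame(
        {
            "gene": effects.index,
            "fraction_top": fraction.to_numpy(),
            "is_common_essential": (fraction >= line_frac).to_numpy(),
        }
    )


def dependent_fraction(
    dep: pd.DataFrame, gene: str, threshold: float = 0.5
) -> DependentFraction:
    """Fraction of lines dependent on ``gene`` (probability strictly > threshold).

    Lines with a missing probability for the gene are excluded from the
    denominator.
    """
    if gene not in dep.index:
        raise KeyError(f"gene {gene!r} not present in the dependency matrix")
    row = dep.loc[gene].dropna().astype(float)
    if ((row < 0) | (row > 1)).any():
        raise ValueError("dependency probabilities must lie in [0, 1]")
    n_dep = int((row > threshold).sum())
    n_tot = int(row.size)
    return DependentFraction(n_dep, n_tot, n_dep / n_tot if n_tot else float("nan"))


def codependency_scan(effects: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Pearson correlation of every gene's effect profile against a query gene.

    For each gene, r is computed over the lines where both the query and
    that gene are scored (pairwise deletion), with a t-distribution p-value
    and BH q-values across all testable genes.  Genes with fewer than 3
    shared lines or a constant profile get NaN and are excluded from the
    adjustment.  The output (gene, r, p, q, n) is volcano-plot ready.
    """
    if gene not in effects.index:
        raise KeyError(f"gene {gene!r} not present in the effects matrix")
    query = effects.loc[gene].astype(float)
    if query.dropna().nunique() <= 1:
        raise UndefinedCorrelationError("query gene is constant across lines")

    mat = effects.to_numpy(dtype=float)
    q = query.to_numpy(dtype=float)
    valid_q = ~np.isnan(q)
    valid = ~np.isnan(mat) & valid_q  # per (gene, line) pairwise mask
    n = valid.sum(axis=1)

    qm = np.where(valid, q, 0.0)
    xm = np.where(valid, mat, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_q = qm.sum(axis=1) / n
        mean_x = xm.sum(axis=1) / n
        cov = (qm * xm).sum(axis=1) / n - mean_q * mean_x
        var_q = (qm**2).sum(axis=1) / n - mean_q**2
        var_x = (xm**2).sum(axis=1) / n - mean_x**2
        r = cov / np.sqrt(var_q * var_x)
    r = np.clip(r, -1.0, 1.0)
    usable = (n >= 3) & (var_q > 0) & (var_x > 0)
    r = np.where(usable, r, np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    p = np.where(usable, p, np.nan)

    qvals = np.full(r.size, np.nan)
    if usable.any():
        qvals[usable] = bh_adjust(p[usable])
    return pd.DataFrame(
        {"gene": effects.index, "r": r, "p_value": p, "q_value": qvals, "n": n}
    )
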
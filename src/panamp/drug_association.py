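"""Expression / drug-response association across cell lines.

Drug response is summarised as the area under the dose–response curve
(AUC) scaled into [0, 1], lower meaning more sensitive.  Two views are
provided: a median split of expression followed by a Mann–Whitney group
comparison of AUC, and a direct Pearson correlation between expression and
AUC, optionally on a mutation-defined subset of lines (e.g. BRCA1/2
wild-type only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from panamp.core_stats import mann_whitney, pearson

__all__ = [
    "AUCCompareResult",
    "CorrelationResult",
    "ExpressionGroups",
    "ScaledAUC",
    "expr_auc_correlation",
    "group_auc_compare",
    "median_split",
    "scale_auc",
]


class ScaledAUC(NamedTuple):
    values: np.ndarray
    n_clipped: int


@dataclass(frozen=True)
class ExpressionGroups:
    """High/low expression partition of cell lines at the median."""

    labels: pd.Series  # "high" / "low", indexed by line id
    median: float

    @property
    def high(self) -> pd.Index:
        return self.labels.index[self.labels == "high"]

    @property
    def low(self) -> pd.Index:
        return self.labels.index[self.labels == "low"]


class AUCCompareResult(NamedTuple):
    statistic: float
    p_value: float
    median_high: float
    median_low: float
    n_high: int
    n_low: int


class CorrelationResult(NamedTuple):
    r: float
    p_value: float
    n: int


def scale_auc(raw_auc: Sequence[float]) -> ScaledAUC:
    """Clip AUC values into [0, 1], reporting how many entries were clipped.

    Re-deriving AUC from dose–response curves is upstream of this package;
    here out-of-range values (from extrapolated curve fits) are clamped.
    """
    a = np.asarray(raw_auc, dtype=float)
    if a.size == 0 or not np.all(np.isfinite(a)):
        raise ValueError("AUC vector must be non-empty and finite")
    clipped = np.clip(a, 0.0, 1.0)
    return ScaledAUC(values=clipped, n_clipped=int((clipped != a).sum()))


def median_split(expr: pd.Series) -> ExpressionGroups:
    """Split lines at the median expression: strictly above -> high, rest -> low.

    Ties at the median go to the low group for determinism.  Requires at
    least 4 lines and a non-degenerate high group.
    """
    e = expr.dropna().astype(float)
    if e.size < 4:
        raise ValueError("need at least 4 lines for a median split")
    med = float(e.median())
    labels = pd.Series(np.where(e > med, "high", "low"), index=e.index)
    if (labels == "high").sum() == 0:
        raise ValueError("high group is empty (constant or heavily tied expression)")
    return ExpressionGroups(labels=labels, median=med)


def _drug_slice(table: pd.DataFrame, drug: str) -> pd.Series:
    for col in ("line", "drug", "auc"):
        if col not in table.columns:
            raise ValueError("drug table must have columns (line, drug, auc)")
    sub = table[table["drug"] == drug]
    if sub.empty:
        raise KeyError(f"drug {drug!r} not present in the response table")
    if sub["line"].duplicated().any():
        raise ValueError(f"duplicate lines for drug {drug!r}")
    return sub.set_index("line")["auc"].astype(float)


def group_auc_compare(
    table: pd.DataFrame, groups: ExpressionGroups, drug: str
) -> AUCCompareResult:
    """Mann–Whitney comparison of AUC between high and low expression lines.

    Restricted to lines present in both the drug table and the grouping;
    direction is reported through the group medians (median_high >
    median_low indicates a resistance association).
    """
    auc = _drug_slice(table, drug)
    high = auc.reindex(groups.high).dropna()
    low = auc.reindex(groups.low).dropna()
    if high.empty or low.empty:
        raise ValueError("one expression group has no AUC measurements")
    u, p = mann_whitney(high.to_numpy(), low.to_numpy())
    return AUCCompareResult(
        statistic=u,
        p_value=p,
        median_high=float(high.median()),
        median_low=float(low.median()),
        n_high=int(high.size),
        n_low=int(low.size),
    )


def expr_auc_correlation(
    table: pd.DataFrame,
    expr: pd.Series,
    drug: str,
    subset: pd.Series | None = None,
) -> CorrelationResult:
    """Pearson correlation between expression and a drug's AUC over shared lines.

    ``subset`` is an optional boolean mask by line id (e.g. mutation
    wild-type status) applied before the correlation.  Raises if fewer than
    3 lines remain.
    """
    auc = _drug_slice(table, drug)
    common = auc.index.intersection(expr.dropna().index)
    if subset is not None:
        keep = subset.reindex(common).fillna(False).astype(bool)
        common = common[keep.to_numpy()]
    if len(common) < 3:
        raise ValueError(f"insufficient data: only {len(common)} shared line(s)")
    r, p = pearson(expr.loc[common].to_numpy(), auc.loc[common].to_numpy())
    return CorrelationResult(r=r, p_value=p, n=len(common))
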
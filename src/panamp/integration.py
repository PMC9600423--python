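"""Criteria integration across cancer types.

Each cancer type is summarised by four boolean flags computed upstream:

* ``upregulated`` — tumour-vs-normal expression test significant with the
  tumour median higher,
* ``prognostic`` — minimum-p-value survival split significant with the
  high-expression group faring worse,
* ``cn_corr`` — per-type copy-number/expression Pearson r at or above a
  threshold,
* ``amplified`` — amplified-sample proportion at or above a threshold.

The intersection table counts cancer types in every flag combination; the
types satisfying all four are the integration hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import pandas as pd

__all__ = ["IntegrationResult", "summarize_types"]

FLAGS = ("upregulated", "prognostic", "cn_corr", "amplified")

#: columns summarize_types expects, with the statistic each flag is cut from
REQUIRED_COLUMNS = (
    "up_q",            # tumour-vs-normal q-value
    "up_tumor_higher", # bool: tumour median above normal
    "surv_p",          # min-p split log-rank p
    "surv_high_worse", # bool: high-expression group has worse survival
    "cn_r",            # per-type CN-expression Pearson r
    "amp_prop",        # fraction of samples called amplified
)


@dataclass(frozen=True)
class IntegrationResult:
    flags: pd.DataFrame            # boolean flags per evaluable cancer type
    combination_counts: pd.DataFrame  # 16-row table: flag combination -> count
    n_evaluable: int
    not_evaluable: tuple[str, ...]
    thresholds: dict = field(default_factory=dict)

    @property
    def full_intersection(self) -> pd.Index:
        """Cancer types satisfying all four criteria."""
        return self.flags.index[self.flags.all(axis=1)]


def summarize_types(
    stats: pd.DataFrame,
    alpha: float = 0.05,
    r_min: float = 0.6,
    f_min: float = 0.1,
) -> IntegrationResult:
    """Evaluate the four per-type criteria and count every flag combination.

    ``stats`` is indexed by cancer type with the columns listed in
    ``REQUIRED_COLUMNS``.  Types with any missing statistic are reported as
    not evaluable and excluded from the counts.  Counts over all 16
    combinations sum to the number of evaluable types.
    """
    missing_cols = set(REQUIRED_COLUMNS) - set(stats.columns)
    if missing_cols:
        raise ValueError(f"missing per-type statistics: {sorted(missing_cols)}")
    if stats.index.has_duplicates:
        raise ValueError("cancer-type labels must be unique")

    complete = stats[list(REQUIRED_COLUMNS)].notna().all(axis=1)
    not_evaluable = tuple(stats.index[~complete])
    s = stats.loc[complete]

    flags = pd.DataFrame(
        {
            "upregulated": (s["up_q"] < alpha) & s["up_tumor_higher"].astype(bool),
            "prognostic": (s["surv_p"] < alpha) & s["surv_high_worse"].astype(bool),
            "cn_corr": s["cn_r"] >= r_min,
            "amplified": s["amp_prop"] >= f_min,
        },
        index=s.index,
    )

    counts = (
        flags.groupby(list(FLAGS)).size() if len(flags) else pd.Series(dtype=int)
    )
    rows = []
    for combo in product([False, True], repeat=len(FLAGS)):
        rows.append({**dict(zip(FLAGS, combo)), "count": int(counts.get(combo, 0))})
    combination_counts = pd.DataFrame(rows)

    return IntegrationResult(
        flags=flags,
        combination_counts=combination_counts,
        n_evaluable=int(complete.sum()),
        not_evaluable=not_evaluable,
        thresholds={"alpha": alpha, "r_min": r_min, "f_min": f_min},
    )
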
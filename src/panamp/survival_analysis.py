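"""Kaplan–Meier estimation, log-rank testing, and minimum-p-value cutpoints.

A survival table holds one row per patient: follow-up ``time``, ``event``
indicator (1 = event observed, 0 = censored) and a continuous ``marker``
(typically expression) to dichotomize.  The minimum-p-value approach scans
every feasible cutpoint on the marker and keeps the one minimising the
log-rank p.  That selected p is reported uncorrected, as is conventional in
the literature this emulates, and is therefore anti-conservative — a
property asserted (not corrected) by the test suite and flagged in the
result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CutpointResult",
    "KMCurve",
    "LogRankResult",
    "km_estimate",
    "logrank_test",
    "min_p_split",
]

REQUIRED_COLUMNS = ("time", "event")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve: event times, S(t), and numbers at risk."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def evaluate(self, t: float) -> float:
        """Step-function value of S at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    degrees_of_freedom: int = 1


@dataclass(frozen=True)
class CutpointResult:
    """Outcome of a minimum-p-value marker dichotomization.

    ``scan`` records every feasible (cutpoint, p) pair so the selection is
    auditable; ``p_value`` is the minimum over the scan and is NOT corrected
    for the multiplicity of candidate cutpoints.
    """

    cutpoint: float
    p_value: float
    n_low: int
    n_high: int
    scan: pd.DataFrame
    multiple_testing_corrected: bool = False


def _validate_table(table: pd.DataFrame, need_marker: bool = False) -> pd.DataFrame:
    cols = REQUIRED_COLUMNS + (("marker",) if need_marker else ())
    if not set(cols).issubset(table.columns):
        raise ValueError(f"survival table must have columns {cols}")
    if len(table) == 0:
        raise ValueError("survival table is empty")
    t = table["time"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or t.min() < 0:
        raise ValueError("times must be finite and nonnegative")
    if not table["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (event)")
    return table


def km_estimate(table: pd.DataFrame) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Patients censored exactly at an event time are counted at risk at that
    time (the standard convention).  With no censoring the curve equals the
    empirical survival function.
    """
    _validate_table(table)
    time = table["time"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=int)
    event_times = np.unique(time[event == 1])
    if event_times.size == 0:
        return KMCurve(
            times=np.array([]), survival=np.array([]), at_risk=np.array([], dtype=int)
        )
    at_risk = np.array([(time >= t).sum() for t in event_times])
    deaths = np.array([((time == t) & (event == 1)).sum() for t in event_times])
    survival = np.cumprod(1.0 - deaths / at_risk)
    return KMCurve(times=event_times, survival=survival, at_risk=at_risk)


def _logrank_arrays(
    time_a: np.ndarray, event_a: np.ndarray, time_b: np.ndarray, event_b: np.ndarray
) -> LogRankResult:
    """Two-group log-rank with hypergeometric variance, chi-square(1) p."""
    times = np.concatenate([time_a, time_b])
    events = np.concatenate([event_a, event_b])
    in_a = np.zeros(times.size, dtype=bool)
    in_a[: time_a.size] = True

    event_times = np.unique(times[events == 1])
    # at-risk counts per group at each event time, vectorised via sorted search
    sa = np.sort(time_a)
    sb = np.sort(time_b)
    n_a = sa.size - np.searchsorted(sa, event_times, side="left")
    n_b = sb.size - np.searchsorted(sb, event_times, side="left")
    n_tot = n_a + n_b

    ea_times = np.sort(times[(events == 1) & in_a])
    all_ev = np.sort(times[events == 1])
    d_a = np.searchsorted(ea_times, event_times, side="right") - np.searchsorted(
        ea_times, event_times, side="left"
    )
    d = np.searchsorted(all_ev, event_times, side="right") - np.searchsorted(
        all_ev, event_times, side="left"
    )

    expected = d * n_a / n_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        var = d * (n_a / n_tot) * (n_b / n_tot) * (n_tot - d) / (n_tot - 1)
    var = np.where(n_tot > 1, var, 0.0)
    observed_minus_expected = float((d_a - expected).sum())
    v = float(var.sum())
    if v <= 0.0:
        return LogRankResult(chi_square=0.0, p_value=1.0)
    chi2 = observed_minus_expected**2 / v
    return LogRankResult(chi_square=chi2, p_value=float(stats.chi2.sf(chi2, df=1)))


def logrank_test(table_a: pd.DataFrame, table_b: pd.DataFrame) -> LogRankResult:
    """Standard two-group log-rank test.

    Observed-minus-expected events in group A are accumulated over the
    pooled distinct event times with the hypergeometric variance; the
    statistic is referred to chi-square with 1 degree of freedom.
    """
    _validate_table(table_a)
    _validate_table(table_b)
    if table_a["event"].sum() + table_b["event"].sum() == 0:
        raise ValueError("no events in the pooled data; log-rank undefined")
    return _logrank_arrays(
        table_a["time"].to_numpy(dtype=float),
        table_a["event"].to_numpy(dtype=int),
        table_b["time"].to_numpy(dtype=float),
        table_b["event"].to_numpy(dtype=int),
    )


def min_p_split(table: pd.DataFrame, min_group_frac: float = 0.1) -> CutpointResult:
    """Dichotomize a continuous marker at the log-rank-minimising cutpoint.

    Candidate cutpoints are the midpoints between consecutive distinct
    marker values for which both resulting groups hold at least
    ``min_group_frac`` of the patients (the maximally-selected-rank-statistic
    convention).  Patients with marker exactly at the cutpoint fall in the
    low group.  Ties at the minimum p are broken toward the more balanced
    split, then toward the lower cutpoint, so the output is deterministic.
    """
    _validate_table(table, need_marker=True)
    if not 0.0 <= min_group_frac < 0.5:
        raise ValueError("min_group_frac must lie in [0, 0.5)")
    marker = table["marker"].to_numpy(dtype=float)
    time = table["time"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=int)
    distinct = np.unique(marker)
    if distinct.size < 2:
        raise ValueError("marker is constant; no cutpoint exists")
    if event.sum() == 0:
        raise ValueError("no events in the data; log-rank undefined")

    n = marker.size
    min_size = min_group_frac * n
    # pre-sort once; each candidate just partitions the sorted arrays
    order = np.argsort(marker, kind="mergesort")
    m_sorted = marker[order]
    t_sorted = time[order]
    e_sorted = event[order]

    rows = []
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cut = (lo + hi) / 2.0
        split = int(np.searchsorted(m_sorted, cut, side="right"))
        n_low, n_high = split, n - split
        if n_low < min_size or n_high < min_size:
            continue
        res = _logrank_arrays(
            t_sorted[:split], e_sorted[:split], t_sorted[split:], e_sorted[split:]
        )
        rows.append((cut, res.p_value, n_low, n_high))
    if not rows:
        raise ValueError(
            f"no cutpoint leaves both groups >= {min_group_frac:.0%} of patients"
        )
    scan = pd.DataFrame(rows, columns=["cutpoint", "p_value", "n_low", "n_high"])
    best_p = scan["p_value"].min()
    at_min = scan[scan["p_value"] == best_p].copy()
    at_min["imbalance"] = (at_min["n_low"] - at_min["n_high"]).abs()
    best = at_min.sort_values(["imbalance", "cutpoint"], kind="mergesort").iloc[0]
    return CutpointResult(
        cutpoint=float(best["cutpoint"]),
        p_value=float(best["p_value"]),
        n_low=int(best["n_low"]),
        n_high=int(best["n_high"]),
        scan=scan[["cutpoint", "p_value", "n_low", "n_high"]],
    )
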
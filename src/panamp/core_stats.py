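"""Statistical kernel shared by every pipeline stage.

Four procedures: the Poisson binomial distribution (pmf and inclusive upper
tail), Benjamini–Hochberg step-up FDR adjustment, the two-sided Mann–Whitney
U test, and Pearson's product-moment correlation with its t-distribution
p-value.

The Poisson binomial distribution describes the sum of independent Bernoulli
variables with unequal success probabilities ``p_i``.  It is the null model
for amplification recurrence: gene-level amplification indicators across
samples are treated as independent Bernoulli draws with each sample's own
genome-wide amplification rate as the success probability.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "UndefinedCorrelationError",
    "MannWhitneyResult",
    "PearsonResult",
    "bh_adjust",
    "mann_whitney",
    "pearson",
    "poibin_pmf",
    "poibin_upper_tail",
]

#: above this n the exact dynamic-programming convolution hands over to the
#: characteristic-function (DFT) evaluation of the same distribution
_DP_MAX_N = 5000

#: per-group size at or below which the Mann–Whitney p-value is computed by
#: exact enumeration of rank assignments (when the pooled data has no ties)
_EXACT_MAX_N = 8


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested for a constant vector."""


class MannWhitneyResult(NamedTuple):
    statistic: float  # U for the first group
    p_value: float


class PearsonResult(NamedTuple):
    r: float
    p_value: float


def _validate_probs(probs: Sequence[float]) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("probs must be a non-empty 1-D vector")
    if not np.all(np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("every success probability must lie in [0, 1]")
    return p


def _poibin_pmf_dp(p: np.ndarray) -> np.ndarray:
    """Exact O(n^2) convolution of n Bernoulli distributions."""
    n = p.size
    pmf = np.zeros(n + 1)
    pmf[0] = 1.0
    for pi in p:
        # new[k] = old[k]*(1-pi) + old[k-1]*pi; RHS evaluated before assignment
        pmf[1:] = pmf[1:] * (1.0 - pi) + pmf[:-1] * pi
        pmf[0] *= 1.0 - pi
    return pmf


def _poibin_pmf_dft(p: np.ndarray) -> np.ndarray:
    """Characteristic-function evaluation via the discrete Fourier transform.

    pmf_k = (1/m) * sum_l chi(omega*l) * exp(-i*omega*l*k),  m = n+1,
    with chi the product of per-Bernoulli characteristic functions.  Products
    are accumulated as sums of complex logarithms for numerical stability.
    """
    n = p.size
    m = n + 1
    omega = 2j * np.pi / m
    chi = np.empty(m, dtype=complex)
    # chunk the (l, j) grid so memory stays bounded for large n
    chunk = max(1, 8_000_000 // max(n, 1))
    for start in range(0, m, chunk):
        l = np.arange(start, min(start + chunk, m))
        z = 1.0 - p + p * np.exp(omega * l[:, None])
        chi[start : start + l.size] = np.exp(np.log(z).sum(axis=1))
    pmf = np.fft.fft(chi).real / m
    pmf = np.clip(pmf, 0.0, None)
    return pmf / pmf.sum()


def poibin_pmf(probs: Sequence[float], method: str = "auto") -> np.ndarray:
    """Probability mass function of a Poisson binomial variable.

    Parameters
    ----------
    probs
        Success probabilities ``p_i`` of the independent Bernoulli summands,
        one per sample; each must lie in [0, 1].
    method
        ``"dp"`` for the exact dynamic-programming convolution, ``"dft"`` for
        the characteristic-function route, ``"auto"`` (default) to use DP up
        to n = 5000 and DFT beyond.

    Returns
    -------
    numpy.ndarray
        ``P(X = j)`` for ``j = 0..n``; sums to 1 to within 1e-12.
    """
    p = _validate_probs(probs)
    if method == "auto":
        method = "dp" if p.size <= _DP_MAX_N else "dft"
    if method == "dp":
        return _poibin_pmf_dp(p)
    if method == "dft":
        return _poibin_pmf_dft(p)
    raise ValueError(f"unknown method {method!r}")


def poibin_upper_tail(k: int, probs: Sequence[float]) -> float:
    """Inclusive upper tail ``P(X >= k)`` of the Poisson binomial distribution.

    The inclusive convention is the conservative standard for discrete
    tests: the observed count itself contributes to the tail.  ``k = 0``
    returns exactly 1.
    """
    p = _validate_probs(probs)
    k = int(k)
    if not 0 <= k <= p.size:
        raise ValueError(f"k={k} outside the support [0, {p.size}]")
    if k == 0:
        return 1.0
    pmf = poibin_pmf(p)
    # summing from the top keeps relative error small for tiny tails
    tail = float(np.cumsum(pmf[::-1])[::-1][k])
    return min(max(tail, 0.0), 1.0)


def poibin_upper_tail_all(probs: Sequence[float]) -> np.ndarray:
    """``P(X >= k)`` for every ``k = 0..n`` in one pmf evaluation.

    Used by the recurrence test, where one vector of sample rates serves all
    genes and only the observed count differs.
    """
    p = _validate_probs(probs)
    pmf = poibin_pmf(p)
    tail = np.cumsum(pmf[::-1])[::-1]
    tail[0] = 1.0
    return np.clip(tail, 0.0, 1.0)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} ( m * p_(j) / j )`` capped at 1 and mapped back to
    the input order.  Each q is at least its raw p and never exceeds 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D vector")
    if not np.all(np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("every p-value must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: str = "auto",
) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    U is computed from rank sums with average ranks for ties.  In ``auto``
    mode the p-value is exact (enumeration of rank assignments) when both
    groups have at most 8 observations and the pooled data is tie-free;
    otherwise the normal approximation with tie and continuity corrections is
    used.  ``mode`` may force ``"exact"`` or ``"approx"``.

    When every value in both groups is identical the test is degenerate and
    p = 1 is returned by convention so that pipeline sweeps never crash.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must contain finite values only")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return MannWhitneyResult(statistic=a.size * b.size / 2.0, p_value=1.0)
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        use_exact = a.size <= _EXACT_MAX_N and b.size <= _EXACT_MAX_N and not has_ties
    elif mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        use_exact = True
    elif mode == "approx":
        use_exact = False
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    return MannWhitneyResult(statistic=float(res.statistic), p_value=float(res.pvalue))


def pearson(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson product-moment correlation with a t-distribution p-value.

    Requires equal lengths of at least 3 and nonzero variance in both
    vectors; a constant vector raises :class:`UndefinedCorrelationError`.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.ndim != 1 or xv.shape != yv.shape:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    res = stats.pearsonr(xv, yv)
    return PearsonResult(r=float(res.statistic), p_value=float(res.pvalue))
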
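"""Synthetic cohort, screen and drug-response generators.

Every pipeline input the analysis consumes can be generated here with the
statistical structure the method assumes: per-sample background
amplification burdens, seeded recurrently-amplified gene blocks, expression
linearly coupled to the log2 copy-number ratio, exponential survival times
with an expression-dependent hazard, bimodal essential/non-essential CRISPR
gene-effect scores normalised to medians 0 and -1, and drug-response AUC
values linearly coupled to expression.

All generators are pure functions of their spec (including its seed):
identical inputs give bit-identical outputs.  Sub-streams are derived from
the single seed with fixed offsets, so adding a generator never perturbs an
existing one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSpec",
    "ScreenSpec",
    "gene_positions",
    "simulate_cna",
    "simulate_drug_response",
    "simulate_expression",
    "simulate_screen",
    "simulate_survival",
]

# fixed sub-stream offsets: one per generator
_STREAM_CNA = 1
_STREAM_EXPR = 2
_STREAM_SURV = 3
_STREAM_SCREEN = 4
_STREAM_DRUG = 5

#: log2(copy number / 2) threshold above which a cell is amplified
AMP_THRESHOLD = 0.3


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic tumour cohort.

    Defaults describe the cohort used throughout the test battery: 500 genes
    by 200 samples, per-sample background amplification rates uniform on
    [0.05, 0.2], and seeded genes receiving +0.4 excess amplification
    probability on top of the background.
    """

    n_genes: int = 500
    n_samples: int = 200
    background_rate_range: tuple[float, float] = (0.05, 0.2)
    seeded_genes: tuple[int, ...] = ()
    seeded_extra_prob: float = 0.4
    cn_noise_sd: float = 0.1
    expr_coupling: float = 1.0
    expr_noise_sd: float = 0.5
    hazard_log_hr: float = 1.0
    baseline_hazard: float = 0.1
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.background_rate_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("background_rate_range must satisfy 0 <= low <= high <= 1")
        if self.seeded_extra_prob + hi > 1.0 + 1e-12:
            raise ValueError("seeded_extra_prob + background high must not exceed 1")
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("n_genes and n_samples must be >= 1")
        if any(not 0 <= g < self.n_genes for g in self.seeded_genes):
            raise ValueError("seeded gene index out of range")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(self.n_samples)]


@dataclass(frozen=True)
class ScreenSpec:
    """Parameters of a synthetic CRISPR knockout screen.

    Gene-effect scores follow the normalisation convention of pan-cancer
    dependency screens: non-essential genes centred at 0, common essentials
    at -1, more negative meaning stronger depletion.
    """

    n_genes: int = 1000
    n_lines: int = 100
    essential_genes: tuple[int, ...] = tuple(range(20))
    essential_mean: float = -1.0
    nonessential_mean: float = 0.0
    score_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.essential_mean >= self.nonessential_mean:
            raise ValueError("essential_mean must be below nonessential_mean")
        if any(not 0 <= g < self.n_genes for g in self.essential_genes):
            raise ValueError("essential gene index out of range")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def line_ids(self) -> list[str]:
        return [f"L{i:04d}" for i in range(self.n_lines)]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, int(seed)])


def simulate_cna(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a gene x sample log2(CN/2) matrix with known amplification labels.

    Per-sample background rates ``p_i`` are drawn uniformly from
    ``spec.background_rate_range``; each cell is amplified with probability
    ``p_i`` plus ``seeded_extra_prob`` for seeded genes.  Amplified cells
    receive ``0.3 + |N(0.3, cn_noise_sd)|`` (strictly above the calling
    threshold), non-amplified cells a draw of ``N(0, cn_noise_sd)`` truncated
    at 0.3 from above, so the true labels coincide with threshold calls.

    Returns
    -------
    (cn, labels)
        ``cn``: float DataFrame, genes x samples.  ``labels``: boolean
        DataFrame of the same shape marking the amplified cells.
    """
    rng = _rng(spec.seed, _STREAM_CNA)
    lo, hi = spec.background_rate_range
    rates = rng.uniform(lo, hi, size=spec.n_samples)
    prob = np.tile(rates, (spec.n_genes, 1))
    if spec.seeded_genes:
        prob[list(spec.seeded_genes), :] += spec.seeded_extra_prob
    labels = rng.random(prob.shape) < prob

    values = np.empty(prob.shape)
    n_amp = int(labels.sum())
    values[labels] = AMP_THRESHOLD + np.abs(
        rng.normal(AMP_THRESHOLD, spec.cn_noise_sd, size=n_amp)
    )
    sd = max(spec.cn_noise_sd, 1e-12)
    trunc = stats.truncnorm(a=-np.inf, b=AMP_THRESHOLD / sd, loc=0.0, scale=sd)
    values[~labels] = trunc.rvs(size=values.size - n_amp, random_state=rng)

    cn = pd.DataFrame(values, index=spec.gene_ids, columns=spec.sample_ids)
    lab = pd.DataFrame(labels, index=spec.gene_ids, columns=spec.sample_ids)
    return cn, lab


def simulate_expression(cn: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Expression = baseline + coupling * log2(CN/2) + Gaussian noise.

    With coupling ``c``, copy-number spread ``sigma_cn`` and noise
    ``sigma_e``, the per-gene Pearson correlation between copy number and
    expression converges to ``c*sigma_cn / sqrt(c^2*sigma_cn^2 + sigma_e^2)``.
    """
    if cn.shape != (spec.n_genes, spec.n_samples):
        raise ValueError("copy-number matrix does not match the cohort spec")
    rng = _rng(spec.seed, _STREAM_EXPR)
    noise = rng.normal(0.0, spec.expr_noise_sd, size=cn.shape)
    return spec.expr_coupling * cn + noise


def _censor_horizon(times: np.ndarray, target: float, tol: float = 0.02) -> float:
    """Bisect the uniform-censoring horizon T_max so that the expected
    censored fraction, mean(min(t_i, T_max)/T_max), hits ``target`` +- tol."""
    lo, hi = 1e-9, float(times.max()) * 1e6

    def rate(tmax: float) -> float:
        return float(np.mean(np.minimum(times, tmax) / tmax))

    for _ in range(200):
        mid = np.sqrt(lo * hi)  # geometric bisection: rate spans decades
        r = rate(mid)
        if abs(r - target) <= tol:
            return mid
        if r > target:  # too much censoring -> extend horizon
            lo = mid
        else:
            hi = mid
    return mid


def simulate_survival(marker: Sequence[float], spec: CohortSpec) -> pd.DataFrame:
    """Exponential survival times with hazard ``h0 * exp(log_hr * marker)``.

    Censoring is independent uniform on ``(0, T_max)`` with ``T_max`` chosen
    by bisection so the realised censoring fraction approximates
    ``spec.censor_rate``.  Returns a table with columns ``time`` (follow-up),
    ``event`` (1 = event observed, 0 = censored) and ``marker``.
    """
    m = np.asarray(marker, dtype=float)
    if m.ndim != 1 or m.size == 0:
        raise ValueError("marker must be a non-empty 1-D vector")
    rng = _rng(spec.seed, _STREAM_SURV)
    hazard = spec.baseline_hazard * np.exp(spec.hazard_log_hr * m)
    event_times = rng.exponential(1.0 / hazard)
    if spec.censor_rate <= 0.0:
        time, event = event_times, np.ones(m.size, dtype=int)
    else:
        tmax = _censor_horizon(event_times, spec.censor_rate)
        censor_times = rng.uniform(0.0, tmax, size=m.size)
        time = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    return pd.DataFrame({"time": time, "event": event, "marker": m})


def simulate_screen(spec: ScreenSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate gene-effect and dependency-probability matrices.

    Essential genes draw scores from ``N(essential_mean, sd)`` and the rest
    from ``N(nonessential_mean, sd)`` independently per line.  The
    probability matrix is a logistic transform of the negated score
    calibrated so a score of -1 maps to a dependency probability of 0.9 and
    a score of 0 to 0.1.
    """
    rng = _rng(spec.seed, _STREAM_SCREEN)
    means = np.full(spec.n_genes, spec.nonessential_mean)
    if spec.essential_genes:
        means[list(spec.essential_genes)] = spec.essential_mean
    scores = rng.normal(means[:, None], spec.score_sd, size=(spec.n_genes, spec.n_lines))
    # logistic in -score through (0, 0.1) and (1, 0.9): slope 2*logit(0.9)
    k = 2.0 * np.log(9.0)
    prob = 1.0 / (1.0 + np.exp(-k * (-scores - 0.5)))
    effects = pd.DataFrame(scores, index=spec.gene_ids, columns=spec.line_ids)
    dep = pd.DataFrame(prob, index=spec.gene_ids, columns=spec.line_ids)
    return effects, dep


def simulate_drug_response(
    expr: Sequence[float],
    slope: float,
    noise_sd: float,
    seed: int,
    drug: str = "drug",
    line_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """AUC = clip(0.5 + slope * standardised expression + noise, 0, 1).

    A positive slope emulates a resistance association (higher expression,
    higher AUC, cisplatin-like); a negative slope a sensitising one
    (Olaparib-like).  Returns a long-format table (line, drug, auc).
    """
    e = np.asarray(expr, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise ValueError("expr must be a 1-D vector with at least 2 lines")
    if np.ptp(e) == 0.0:
        raise ValueError("expression is constant; cannot standardise")
    rng = _rng(seed, _STREAM_DRUG)
    z = (e - e.mean()) / e.std()
    auc = np.clip(0.5 + slope * z + rng.normal(0.0, noise_sd, size=e.size), 0.0, 1.0)
    if line_ids is None:
        line_ids = [f"L{i:04d}" for i in range(e.size)]
    return pd.DataFrame({"line": list(line_ids), "drug": drug, "auc": auc})


def gene_positions(
    genes: Sequence[str],
    genes_per_chrom: int = 100,
    gene_span: int = 1_000_000,
) -> pd.DataFrame:
    """Deterministic genome layout for synthetic genes.

    Genes are tiled in input order onto consecutive chromosomes,
    ``genes_per_chrom`` per chromosome, each occupying a ``gene_span`` window
    (0-based, half-open).  Good enough to exercise genome-ordered frequency
    tracks; no attempt at a realistic karyotype.
    """
    records = []
    for i, g in enumerate(genes):
        chrom = f"chr{i // genes_per_chrom + 1}"
        start = (i % genes_per_chrom) * gene_span
        records.append((g, chrom, start, start + gene_span))
    return pd.DataFrame(records, columns=["gene", "chrom", "start", "end"])
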
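import numpy as np
import pandas as pd
import pytest

from panamp import CohortSpec, ScreenSpec, simulate_cna, simulate_expression


def poibin_tail_bruteforce(k: int, probs) -> float:
    """Independent oracle: P(X >= k) by enumerating all 2^n Bernoulli outcomes."""
    probs = np.asarray(probs, dtype=float)
    n = probs.size
    masks = np.arange(2**n)[:, None] >> np.arange(n) & 1  # rows = outcomes
    counts = masks.sum(axis=1)
    outcome_probs = np.prod(np.where(masks == 1, probs, 1.0 - probs), axis=1)
    return float(outcome_probs[counts >= k].sum())


@pytest.fixture(scope="session")
def small_cohort():
    """120 genes x 60 samples, 3 seeded genes, for fast end-to-end checks."""
    spec = CohortSpec(
        n_genes=120,
        n_samples=60,
        seeded_genes=(0, 1, 2),
        seeded_extra_prob=0.4,
        seed=11,
    )
    cn, labels = simulate_cna(spec)
    expr = simulate_expression(cn, spec)
    return spec, cn, labels, expr


@pytest.fixture(scope="session")
def screen_matrices():
    spec = ScreenSpec(n_genes=300, n_lines=40, essential_genes=tuple(range(10)), seed=7)
    from panamp import simulate_screen

    effects, dep = simulate_screen(spec)
    return spec, effects, dep
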
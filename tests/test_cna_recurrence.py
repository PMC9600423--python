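"""Amplification calling and recurrence testing."""

import warnings

import numpy as np
import pandas as pd
import pytest

from panamp import (
    CohortSpec,
    call_amplification,
    cn_expression_summary,
    frequency_track,
    gene_positions,
    group_expression_compare,
    recurrence_test,
    sample_rates,
    simulate_cna,
    simulate_expression,
)


def _amp_from(values, genes=None, samples=None, threshold=0.3):
    df = pd.DataFrame(
        values,
        index=genes or [f"g{i}" for i in range(len(values))],
        columns=samples or [f"s{j}" for j in range(len(values[0]))],
    )
    return call_amplification(df, threshold=threshold)


class TestCallAmplification:
    def test_strict_threshold_boundary(self):
        amp = _amp_from([[0.31, 0.30, 0.29]])
        assert list(amp.calls.iloc[0]) == [1, 0, 0]

    def test_epsilon_above_is_amplified(self):
        amp = _amp_from([[0.3 + 1e-12]])
        assert amp.calls.iloc[0, 0] == 1

    def test_all_zero_matrix(self):
        amp = _amp_from([[0.0, 0.0], [0.0, 0.0]])
        assert not amp.calls.to_numpy().any()

    def test_deletions_are_not_amplifications(self):
        amp = _amp_from([[-0.8, -0.31, 0.8]])
        assert list(amp.calls.iloc[0]) == [0, 0, 1]

    def test_missing_calls_zero_and_reported(self):
        amp = _amp_from([[np.nan, 0.5], [0.1, np.nan]])
        assert amp.calls.to_numpy().tolist() == [[0, 1], [0, 0]]
        assert amp.n_missing.tolist() == [1, 1]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            call_amplification(pd.DataFrame())


class TestSampleRates:
    def test_counting(self):
        amp = _amp_from([[1.0], [0.4], [0.5], [0.0], [0.1], [0.2], [0.0], [0.0], [0.0], [0.0]])
        assert sample_rates(amp).iloc[0] == pytest.approx(0.3)

    def test_fully_amplified_sample(self):
        amp = _amp_from([[1.0, 0.0], [2.0, 0.0]])
        assert sample_rates(amp).tolist() == [1.0, 0.0]


class TestRecurrenceTest:
    def test_zero_count_gene_has_p_one(self):
        amp = _amp_from([[0.0, 0.0, 0.0], [0.5, 0.5, 0.0]])
        rec = recurrence_test(amp).set_index("gene")
        assert rec.loc["g0", "p_value"] == 1.0

    def test_full_count_equals_product_of_rates(self):
        # 10 genes x 3 samples engineered to rates (0.1, 0.2, 0.3): a gene
        # amplified in all three samples has p = 0.1*0.2*0.3 = 0.006
        values = np.zeros((10, 3))
        values[0, :] = 0.5  # g0 amplified everywhere
        values[1, 1] = 0.5
        values[2, 2] = 0.5
        values[3, 2] = 0.5
        amp = _amp_from(values.tolist())
        assert sample_rates(amp).tolist() == pytest.approx([0.1, 0.2, 0.3])
        rec = recurrence_test(amp).set_index("gene")
        assert rec.loc["g0", "p_value"] == pytest.approx(0.006, abs=1e-12)

    def test_seeded_genes_detected(self, small_cohort):
        spec, cn, labels, _ = small_cohort
        rec = recurrence_test(call_amplification(cn)).set_index("gene")
        seeded = [f"G{i:04d}" for i in spec.seeded_genes]
        assert (rec.loc[seeded, "q_value"] < 0.05).all()

    def test_permuting_samples_leaves_records_unchanged(self, small_cohort):
        _, cn, _, _ = small_cohort
        rec = recurrence_test(call_amplification(cn))
        rng = np.random.default_rng(0)
        shuffled = cn.iloc[:, rng.permutation(cn.shape[1])]
        rec2 = recurrence_test(call_amplification(shuffled))
        pd.testing.assert_frame_equal(rec, rec2)

    def test_monotone_in_count(self):
        # raising one gene's count, rates held fixed, cannot raise its p
        rng = np.random.default_rng(1)
        base = (rng.random((40, 25)) < 0.15).astype(float)
        amp = _amp_from((base * 0.5).tolist())
        rates = sample_rates(amp)
        from panamp.core_stats import poibin_upper_tail

        tails = [poibin_upper_tail(k, rates.to_numpy()) for k in range(26)]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))

    def test_sorted_by_q_then_p_then_gene(self, small_cohort):
        _, cn, _, _ = small_cohort
        rec = recurrence_test(call_amplification(cn))
        key = list(zip(rec["q_value"], rec["p_value"], rec["gene"]))
        assert key == sorted(key)

    def test_null_p_values_not_anticonservative(self):
        hits = trials = 0
        for seed in range(5):
            spec = CohortSpec(n_genes=300, n_samples=80, seeded_genes=(), seed=seed)
            cn, _ = simulate_cna(spec)
            rec = recurrence_test(call_amplification(cn))
            hits += (rec["p_value"] <= 0.05).sum()
            trials += len(rec)
        sigma = np.sqrt(0.05 * 0.95 / trials)
        assert hits / trials <= 0.05 + 3 * sigma

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            recurrence_test(_amp_from([[0.5]]))


class TestFrequencyTrack:
    def test_order_and_conservation(self, small_cohort):
        _, cn, _, _ = small_cohort
        amp = call_amplification(cn)
        pos = gene_positions(list(cn.index), genes_per_chrom=50)
        track = frequency_track(amp, pos)
        assert len(track) == cn.shape[0]
        # frequencies equal row means of the call matrix
        freq = amp.calls.mean(axis=1)
        merged = track.set_index("gene")["frequency"]
        assert np.allclose(merged.loc[freq.index], freq)
        # within each chromosome the track is start-ordered
        for _, grp in track.groupby("chrom", sort=False):
            assert grp["start"].is_monotonic_increasing

    def test_seeded_block_is_the_maximum(self, small_cohort):
        spec, cn, _, _ = small_cohort
        amp = call_amplification(cn)
        track = frequency_track(amp, gene_positions(list(cn.index)))
        top = track.sort_values("frequency", ascending=False).head(len(spec.seeded_genes))
        assert set(top["gene"]) == {f"G{i:04d}" for i in spec.seeded_genes}

    def test_missing_positions_warned_and_excluded(self, small_cohort):
        _, cn, _, _ = small_cohort
        amp = call_amplification(cn)
        pos = gene_positions(list(cn.index)[:-3])
        with pytest.warns(UserWarning, match="without positions"):
            track = frequency_track(amp, pos)
        assert len(track) == cn.shape[0] - 3

    def test_empty_positions_rejected(self, small_cohort):
        _, cn, _, _ = small_cohort
        with pytest.raises(ValueError):
            frequency_track(call_amplification(cn), pd.DataFrame())


class TestCnExpressionSummary:
    def test_coupled_group_correlates(self, small_cohort):
        spec, cn, _, expr = small_cohort
        labels = pd.Series("typeA", index=cn.columns)
        out = cn_expression_summary(cn, expr, "G0000", labels)
        assert out.loc[0, "r"] > 0.3
        assert out.loc[0, "p_value"] < 0.01
        assert out.loc[0, "n"] == spec.n_samples

    def test_perfect_coupling_limit(self):
        cn = pd.DataFrame([[0.0, 0.2, 0.5, 0.9]], index=["g"], columns=list("abcd"))
        expr = cn * 2.0
        labels = pd.Series("t", index=cn.columns)
        out = cn_expression_summary(cn, expr, "g", labels)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_unamplified_group_proportion_zero(self):
        cn = pd.DataFrame([[0.0, 0.1, 0.2, 0.25]], index=["g"], columns=list("abcd"))
        expr = cn + 0.01
        labels = pd.Series("t", index=cn.columns)
        out = cn_expression_summary(cn, expr, "g", labels)
        assert out.loc[0, "prop_amplified"] == 0.0


def test_group_expression_compare_reports_medians():
    res = group_expression_compare([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
    assert res.p_value == pytest.approx(0.1)
    assert res.median_a == 6.0 and res.median_b == 2.0
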
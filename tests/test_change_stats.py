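"""Reliable change, group comparisons, pre/post models, and BH-FDR."""

import numpy as np
import pytest
from scipy import stats

from icapkit import change_stats as cs


class TestRCI:
    def test_no_change_gives_zero(self):
        assert cs.reliable_change(10.0, 10.0, 2.0).rci == 0.0

    def test_direct_formula(self):
        assert cs.reliable_change(10.0, 16.0, 3.0).rci == pytest.approx(2.0)

    def test_doubling_sem_halves_rci(self):
        r1 = cs.reliable_change(5.0, 11.0, 2.0).rci
        r2 = cs.reliable_change(5.0, 11.0, 4.0).rci
        assert r1 == pytest.approx(2 * r2)

    def test_antisymmetric_under_swapping_timepoints(self):
        a = cs.reliable_change(12.0, 20.0, 3.0).rci
        b = cs.reliable_change(20.0, 12.0, 3.0).rci
        assert a == pytest.approx(-b)

    def test_nonpositive_sem_raises(self):
        with pytest.raises(ValueError):
            cs.reliable_change(1.0, 2.0, 0.0)

    def test_sem_d_estimator(self):
        assert cs.estimate_sem_d(10.0, 0.0) == pytest.approx(10 * np.sqrt(2))
        assert cs.estimate_sem_d(10.0, 0.5) == pytest.approx(10.0)
        assert cs.estimate_sem_d(10.0, 0.999) < 0.5

    def test_reliability_out_of_range_raises(self):
        with pytest.raises(ValueError):
            cs.estimate_sem_d(10.0, 1.0)

    def test_rci_frame_estimates_reliability_in_sample(self):
        rng = np.random.default_rng(0)
        before = rng.normal(50, 10, 40)
        after = before + rng.normal(2, 3, 40)
        f = cs.rci_frame(before, after, measure="m")
        r = np.corrcoef(before, after)[0, 1]
        expected = cs.estimate_sem_d(before.std(ddof=1), r)
        np.testing.assert_allclose(f["sem_d"], expected)
        np.testing.assert_allclose(f["rci"], (after - before) / expected)


class TestGroupComparisons:
    def test_equal_groups_give_zero_t(self):
        res = cs.pooled_two_sample_t(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.statistic == 0.0

    def test_cohort_table_birth_weight(self):
        res = cs.pooled_two_sample_t(1197.66, 397.40, 32, 3443.96, 452.92, 24)
        assert res.df == 54
        assert res.statistic == pytest.approx(-19.715, rel=5e-3)
        assert res.p < 0.001

    def test_cohort_table_gestational_age(self):
        res = cs.pooled_two_sample_t(29.07, 1.99, 32, 39.89, 1.54, 24)
        assert res.statistic == pytest.approx(-22.153, rel=5e-3)

    def test_cohort_table_general_ability(self):
        res = cs.pooled_two_sample_t(108.12, 10.55, 32, 116.46, 11.04, 24)
        assert res.statistic == pytest.approx(-2.867, rel=5e-3)

    def test_chi_square_sex_distribution(self):
        res = cs.chi_square_2x2(18, 14, 9, 15)
        assert res.statistic == pytest.approx(1.931, abs=5e-4)
        assert res.df == 1

    def test_chi_square_independence_gives_zero(self):
        assert cs.chi_square_2x2(10, 10, 10, 10).statistic == 0.0

    def test_chi_square_matches_direct_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b, c, d = rng.integers(1, 40, 4)
            res = cs.chi_square_2x2(a, b, c, d)
            table = np.array([[a, b], [c, d]], dtype=float)
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            oracle = ((table - expected) ** 2 / expected).sum()
            assert res.statistic == pytest.approx(oracle)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            cs.chi_square_2x2(0, 0, 5, 5)


class TestGroupModel:
    def test_equals_pooled_t_without_covariate(self):
        rng = np.random.default_rng(2)
        g1 = rng.normal(0, 1, 15)
        g2 = rng.normal(0.8, 1, 12)
        scores = np.concatenate([g1, g2])
        group = np.array(["a"] * 15 + ["b"] * 12)
        res = cs.group_model(scores, group)
        pooled = cs.pooled_two_sample_t(
            g2.mean(), g2.std(ddof=1), 12, g1.mean(), g1.std(ddof=1), 15
        )
        assert res.statistic == pytest.approx(pooled.statistic, abs=1e-8)
        assert res.df == pooled.df

    def test_recovers_planted_group_shift(self):
        rng = np.random.default_rng(3)
        shift = 1.0
        scores = np.concatenate([rng.normal(0, 1, 30), rng.normal(shift, 1, 30)])
        group = np.repeat(["a", "b"], 30)
        res = cs.group_model(scores, group)
        assert abs(res.estimate - shift) < 0.4

    def test_constant_covariate_raises(self):
        scores = np.arange(12.0)
        group = np.repeat(["a", "b"], 6)
        with pytest.raises(ValueError, match="constant"):
            cs.group_model(scores, group, covariate=np.ones(12))


class TestPrePost:
    def test_no_change_gives_zero_effect(self):
        before = np.arange(10.0)
        res = cs.prepost_model(before, before)
        assert res.estimate == 0.0 and res.p == 1.0

    def test_uniform_shift_estimated_exactly(self):
        before = np.arange(10.0)
        res = cs.prepost_model(before, before + 2.5)
        assert res.estimate == pytest.approx(2.5)
        assert res.p == 0.0

    def test_matches_paired_t_oracle(self):
        rng = np.random.default_rng(4)
        before = rng.normal(50, 8, 25)
        after = before + rng.normal(1.5, 2, 25)
        res = cs.prepost_model(before, after)
        t, p = stats.ttest_rel(after, before)
        assert res.statistic == pytest.approx(t, abs=1e-6)
        assert res.p == pytest.approx(p, abs=1e-6)

    def test_random_intercept_model_agrees_with_paired_t(self):
        """Explicit MixedLM time effect equals the paired t on balanced pairs."""
        rng = np.random.default_rng(5)
        n = 20
        subj_eff = rng.normal(0, 5, n)
        before = 50 + subj_eff + rng.normal(0, 2, n)
        after = before + 2 + rng.normal(0, 2, n)
        direct = cs.prepost_model(before, after)
        lmm = cs.prepost_mixedlm(before, after, np.arange(n))
        assert lmm.estimate == pytest.approx(direct.estimate, abs=1e-6)

    def test_nan_rows_raise_pairing_error(self):
        with pytest.raises(ValueError):
            cs.prepost_model(np.array([1.0, np.nan]), np.array([2.0, 3.0]))


def brute_force_bh(pvals):
    n = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, pvals[i] * n / rank)
        q[i] = prev
    return q


class TestFDR:
    def test_single_p_unchanged(self):
        q, flags = cs.bh_fdr(np.array([0.03]))
        assert q[0] == pytest.approx(0.03)
        assert flags[0]

    def test_worked_step_up_example(self):
        q, _ = cs.bh_fdr(np.array([0.01, 0.02, 0.03, 0.8]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.8])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.random(rng.integers(2, 30))
            q, _ = cs.bh_fdr(p)
            np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-12)

    def test_flags_monotone_in_p(self):
        rng = np.random.default_rng(7)
        p = rng.random(50) ** 2
        _, flags = cs.bh_fdr(p)
        if flags.any():
            assert flags[p <= p[flags].max()].all()

    def test_q_at_least_p(self):
        rng = np.random.default_rng(8)
        p = rng.random(30)
        q, _ = cs.bh_fdr(p)
        assert np.all(q >= p - 1e-12)

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            cs.bh_fdr(np.array([0.1, 1.2]))
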
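"""Temporal properties: back-projection, trains, durations, Jaccard couplings."""

import numpy as np
import pytest

from icapkit import tempmetrics as tm


def brute_occurrences(train):
    count = 0
    prev = 0
    for v in train:
        if v != 0 and v != prev:
            count += 1
        prev = v
    return count


class TestRegression:
    def test_exact_multiple_of_one_map(self):
        rng = np.random.default_rng(0)
        zmaps = rng.normal(0, 1, (4, 60))
        activity = np.outer(zmaps[0], [3.0, 3.0, 3.0])
        raw, _ = tm.transient_informed_regression(zmaps, activity)
        np.testing.assert_allclose(raw[0], 3.0, atol=1e-8)
        np.testing.assert_allclose(raw[1:], 0.0, atol=1e-8)

    def test_disjoint_maps_give_projection_oracle(self):
        # two maps on disjoint supports with background voxels left over
        zmaps = np.zeros((2, 60))
        zmaps[0, :20] = 1.0
        zmaps[1, 20:40] = 1.0
        zc = zmaps - zmaps.mean(axis=1, keepdims=True)
        rng = np.random.default_rng(1)
        coef = rng.normal(0, 1, (2, 5))
        activity = zc.T @ coef
        raw, _ = tm.transient_informed_regression(zmaps, activity)
        # closed-form normal-equations oracle on the centred maps
        expected = np.linalg.inv(zc @ zc.T) @ zc @ activity
        np.testing.assert_allclose(raw, expected, atol=1e-8)
        np.testing.assert_allclose(raw, coef, atol=1e-8)

    def test_duplicated_map_raises_conditioning_error(self):
        rng = np.random.default_rng(2)
        m = rng.normal(0, 1, 30)
        with pytest.raises(ValueError, match="collinear"):
            tm.transient_informed_regression(
                np.vstack([m, m]), rng.normal(0, 1, (30, 4))
            )

    def test_norm_mask_excludes_scrubbed_volumes_from_stats(self):
        rng = np.random.default_rng(3)
        zmaps = rng.normal(0, 1, (2, 50))
        activity = rng.normal(0, 1, (50, 20))
        keep = np.ones(20, dtype=bool)
        keep[:4] = False
        raw, z = tm.transient_informed_regression(zmaps, activity, norm_mask=keep)
        np.testing.assert_allclose(z[:, keep].mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(z[:, keep].std(axis=1), 1.0, atol=1e-10)


class TestBinarize:
    def test_zero_course_gives_zero_train(self):
        assert not tm.binarize_blocks(np.zeros(10), 1.0).any()

    def test_worked_example(self):
        course = np.array([0.0, 2.0, 2.0, 0.0, -2.0, 0.0])
        train = tm.binarize_blocks(course, 1.0)[0]
        np.testing.assert_array_equal(train, [0, 1, 1, 0, -1, 0])
        assert tm.occurrences(train)[0] == 2

    def test_scrubbed_volume_forced_to_zero(self):
        course = np.array([0.0, 2.0, 2.0, 0.0, -2.0, 0.0])
        keep = np.array([True, True, False, True, True, True])
        train = tm.binarize_blocks(course, 1.0, keep)[0]
        np.testing.assert_array_equal(train, [0, 1, 0, 0, -1, 0])
        assert tm.total_duration(train, keep)[0] == pytest.approx(100 * 2 / 5)

    def test_nonpositive_threshold_raises(self):
        with pytest.raises(ValueError):
            tm.binarize_blocks(np.zeros(5), 0.0)


class TestDurationOccurrences:
    def test_half_active_train(self):
        train = np.array([0, 1, 1, 0, -1, 0])
        assert tm.total_duration(train)[0] == 50.0

    def test_zero_train(self):
        assert tm.total_duration(np.zeros(6))[0] == 0.0

    def test_all_scrubbed_raises(self):
        with pytest.raises(ZeroDivisionError):
            tm.total_duration(np.ones(4), np.zeros(4, dtype=bool))

    def test_random_trains_match_recount_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            train = rng.choice([-1, 0, 0, 1], size=rng.integers(5, 60))
            keep = rng.random(len(train)) > 0.1
            if not keep.any():
                continue
            dur = tm.total_duration(train, keep)[0]
            recount = 100.0 * sum(
                1 for t in range(len(train)) if keep[t] and train[t] != 0
            ) / keep.sum()
            assert dur == pytest.approx(recount)
            assert tm.occurrences(train)[0] == brute_occurrences(train)

    def test_sign_change_without_gap_starts_new_block(self):
        assert tm.occurrences(np.array([1, -1, 1]))[0] == 3

    def test_duration_invariant_under_joint_permutation(self):
        rng = np.random.default_rng(6)
        train = rng.choice([-1, 0, 1], size=40)
        keep = rng.random(40) > 0.2
        perm = rng.permutation(40)
        a = tm.total_duration(train, keep)[0]
        b = tm.total_duration(train[perm], keep[perm])[0]
        assert a == pytest.approx(b)


class TestJaccard:
    def test_identical_trains_couple_fully(self):
        t = np.array([1, 0, -1, 1])
        c, a = tm.coupling_jaccard(t, t)
        assert (c, a) == (1.0, 0.0)

    def test_opposite_trains_anticouple_fully(self):
        c, a = tm.coupling_jaccard([1, 1, 0, 0], [-1, -1, 0, 0])
        assert (c, a) == (0.0, 1.0)

    def test_worked_partial_overlap(self):
        c, a = tm.coupling_jaccard([1, 0, 1, -1], [1, 1, 0, -1])
        assert c == pytest.approx(2 / 4)
        assert a == 0.0

    def test_empty_union_gives_zeros(self):
        assert tm.coupling_jaccard(np.zeros(5), np.zeros(5)) == (0.0, 0.0)

    def test_coupling_plus_anticoupling_bounded_and_symmetric(self):
        rng = np.random.default_rng(7)
        blocks = rng.choice([-1, 0, 1], size=(6, 50))
        m = tm.compute_metrics(blocks)
        assert np.all(m.coupling + m.anticoupling <= 1 + 1e-12)
        np.testing.assert_allclose(m.coupling, m.coupling.T)
        np.testing.assert_allclose(m.anticoupling, m.anticoupling.T)
        assert np.all(np.diag(m.anticoupling) == 0)

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            tm.coupling_jaccard([1, 0], [1, 0, 1])


class TestStaticCorrelation:
    def test_duplicated_course_correlates_fully(self):
        rng = np.random.default_rng(8)
        c = rng.normal(0, 1, 30)
        corr = tm.static_correlation(np.vstack([c, c]))
        assert corr[0, 1] == pytest.approx(1.0)

    def test_orthogonal_centred_courses_uncorrelated(self):
        a = np.array([1.0, -1.0] * 10)
        b = np.array([1.0, 1.0, -1.0, -1.0] * 5)
        corr = tm.static_correlation(np.vstack([a, b]))
        assert abs(corr[0, 1]) < 1e-10

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(9)
        courses = rng.normal(0, 1, (4, 40))
        keep = rng.random(40) > 0.2
        corr = tm.static_correlation(courses, keep)
        expected = np.corrcoef(courses[:, keep])
        np.testing.assert_allclose(corr, expected, atol=1e-12)

    def test_zero_variance_course_flagged_nan(self):
        courses = np.vstack([np.ones(10), np.arange(10.0)])
        corr = tm.static_correlation(courses)
        assert np.isnan(corr[0, 1]) and np.isnan(corr[0, 0])
        assert corr[1, 1] == 1.0


class TestPairLayout:
    def test_eight_icaps_give_28_pairs(self):
        assert len(tm.pair_index(8)) == 28

    def test_metrics_frame_tidy_layout(self):
        blocks = np.array([[0, 1, 1, 0], [1, 0, -1, 0]])
        m = tm.compute_metrics(blocks, subject="s1", session="pre")
        df = tm.metrics_frame([m])
        assert list(df.columns) == [
            "subject", "session", "icap_i", "icap_j", "metric", "value"
        ]
        assert (df.metric == "coupling").sum() == 1  # K=2 -> one pair
        assert df[df.metric == "duration"].value.tolist() == [50.0, 50.0]
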
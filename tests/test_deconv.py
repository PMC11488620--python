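"""Sparse hemodynamic deconvolution: solver correctness and recovery."""

import numpy as np
import pytest
from scipy.optimize import lsq_linear

from icapkit import synth
from icapkit.deconv import (
    deconvolve_session,
    deconvolve_voxel,
    default_lambda,
    hrf_kernel,
    tv_denoise,
)
from icapkit.io import scrub


def tv_objective(y, kernel, s, lam):
    pred = np.convolve(s, kernel)[: len(y)]
    return 0.5 * np.sum((y - pred) ** 2) + lam * np.sum(np.abs(np.diff(s)))


class TestHRF:
    def test_peak_near_six_seconds(self):
        h = hrf_kernel(2.0, 32)
        assert h.argmax() == 3  # t = 6 s at TR 2 s
        assert h.sum() > 0

    def test_length_matches_duration_over_tr(self):
        assert len(hrf_kernel(1.0, 32)) == 32
        assert len(hrf_kernel(2.0, 32)) == 16

    def test_deterministic(self):
        np.testing.assert_array_equal(hrf_kernel(2.0, 32), hrf_kernel(2.0, 32))

    def test_bad_parameters_raise(self):
        with pytest.raises(ValueError):
            hrf_kernel(0.0)
        with pytest.raises(ValueError):
            hrf_kernel(2.0, duration=10)


class TestTautString:
    def test_matches_dual_qp_oracle_on_random_inputs(self):
        """TV prox equals the box-constrained dual QP solved independently."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(3, 50))
            y = rng.normal(0, 1, n) * rng.choice([0.1, 1.0, 10.0])
            lam = float(rng.choice([0.01, 0.1, 1.0, 5.0]))
            d = np.diff(np.eye(n), axis=0)
            dual = lsq_linear(d.T, y, bounds=(-lam, lam), tol=1e-14, max_iter=2000)
            oracle = y - d.T @ dual.x
            np.testing.assert_allclose(tv_denoise(y, lam), oracle, atol=1e-8)

    def test_large_weight_flattens_to_the_mean(self):
        y = np.array([1.0, 5.0, -2.0, 3.0])
        np.testing.assert_allclose(tv_denoise(y, 100.0), np.full(4, y.mean()))


class TestDeconvolveVoxel:
    def test_zero_series_stays_zero(self, kernel_tr2):
        act, innov, trace = deconvolve_voxel(np.zeros(50), kernel_tr2, lam=1.0)
        assert not act.any() and not innov.any()

    def test_noiseless_block_support_within_one_volume(self, kernel_tr2):
        """Innovation support vs exhaustive single-block oracle on the same objective."""
        T = 60
        train = np.zeros(T)
        train[20:30] = 1.0
        y = np.convolve(train, kernel_tr2)[:T]
        lam = 0.05
        act, innov, _ = deconvolve_voxel(y, kernel_tr2, lam, max_iter=800, tol=0)

        # oracle: best single-block signal (onset, offset, amplitude grid)
        best = np.inf
        best_sup = None
        amps = np.linspace(0.5, 1.5, 21)
        for on in range(5, 40):
            for off in range(on + 2, min(on + 20, T)):
                for a in amps:
                    s = np.zeros(T)
                    s[on:off] = a
                    obj = tv_objective(y, kernel_tr2, s, lam)
                    if obj < best:
                        best, best_sup = obj, (on, off)
        assert abs(best_sup[0] - 20) <= 1 and abs(best_sup[1] - 30) <= 1
        sup = np.flatnonzero(np.abs(innov) > 0.1 * np.abs(innov).max())
        assert all(min(abs(s - 20), abs(s - 30)) <= 1 for s in sup)
        # the solver can only do at least as well as the restricted oracle
        assert tv_objective(y, kernel_tr2, act, lam) <= best + 1e-6

    def test_huge_lambda_gives_constant_activity(self, kernel_tr2):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 50)
        act, innov, _ = deconvolve_voxel(y, kernel_tr2, lam=1e4)
        assert np.ptp(act) < 1e-6
        assert np.abs(innov).max() < 1e-6

    def test_nan_series_raises_data_error(self, kernel_tr2):
        y = np.zeros(40)
        y[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            deconvolve_voxel(y, kernel_tr2, lam=1.0)

    def test_objective_monotone_on_random_voxels(self, kernel_tr2):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y = rng.normal(0, 1, 60)
            lam = float(default_lambda(y)[0])
            _, _, trace = deconvolve_voxel(y, kernel_tr2, lam, max_iter=150)
            assert np.all(np.diff(trace) <= 1e-9)

    def test_small_instance_never_beaten_by_two_breakpoint_grid(self, kernel_tr2):
        """Brute-force <=2-breakpoint piecewise-constant grid oracle (T <= 30)."""
        rng = np.random.default_rng(3)
        T = 24
        for trial in range(3):
            y = rng.normal(0, 0.5, T)
            y[8:15] += rng.uniform(0.5, 1.5)
            lam = float(default_lambda(y)[0])
            act, _, _ = deconvolve_voxel(y, kernel_tr2, lam, max_iter=2000, tol=0)
            solver_obj = tv_objective(y, kernel_tr2, act, lam)
            levels = np.linspace(y.min(), y.max(), 7)
            best = np.inf
            for t1 in range(1, T):
                for t2 in range(t1 + 1, T + 1):
                    for a in levels:
                        for b in levels:
                            for c in levels if t2 < T else [b]:
                                s = np.empty(T)
                                s[:t1] = a
                                s[t1:t2] = b
                                s[t2:] = c
                                best = min(best, tv_objective(y, kernel_tr2, s, lam))
            assert solver_obj <= best + 1e-8


class TestDeconvolveSession:
    def test_innovation_edges_match_planted_blocks(self, two_network_phantom):
        atlas, trains, sess = two_network_phantom
        inn = deconvolve_session(sess, max_iter=600, tol=1e-8)
        mask = sess.mask
        edges = {
            0: [15, 25, 50, 60],
            1: [30, 42],
        }
        for k, true_edges in edges.items():
            vox = atlas.maps[k][mask] > 0
            mean_innov = inn.innovations[vox].mean(axis=0)
            sup = np.flatnonzero(np.abs(mean_innov) > 0.2 * np.abs(mean_innov).max())
            for s in sup:
                assert min(abs(s - e) for e in true_edges) <= 1

    def test_noiseless_activity_correlates_with_trains(self, two_network_phantom):
        atlas, trains, sess = two_network_phantom
        inn = deconvolve_session(sess, max_iter=600, tol=1e-8)
        mask = sess.mask
        for k in range(2):
            vox = atlas.maps[k][mask] > 0
            mean_act = inn.activity[vox].mean(axis=0)
            assert np.corrcoef(mean_act, trains[k])[0, 1] > 0.95

    def test_single_voxel_mask_shapes(self, two_network_phantom):
        _, _, sess = two_network_phantom
        mask = np.zeros(sess.data.shape[:3], dtype=bool)
        mask[0, 0, 0] = True
        inn = deconvolve_session(sess, mask=mask, max_iter=50)
        assert inn.activity.shape == (1, sess.n_volumes)
        assert inn.innovations.shape == (1, sess.n_volumes)

    def test_empty_mask_raises(self, two_network_phantom):
        _, _, sess = two_network_phantom
        with pytest.raises(ValueError, match="empty"):
            deconvolve_session(sess, mask=np.zeros(sess.data.shape[:3], dtype=bool))

    def test_rerun_is_deterministic(self, two_network_phantom):
        _, _, sess = two_network_phantom
        a = deconvolve_session(sess, max_iter=100)
        b = deconvolve_session(sess, max_iter=100)
        np.testing.assert_array_equal(a.activity, b.activity)
        np.testing.assert_array_equal(a.innovations, b.innovations)

    def test_differencing_activity_reproduces_innovations(self, two_network_phantom):
        _, _, sess = two_network_phantom
        inn = deconvolve_session(sess, max_iter=100)
        diff = np.diff(inn.activity, axis=1)
        np.testing.assert_allclose(inn.innovations[:, 1:], diff, rtol=1e-8, atol=1e-10)

    def test_objective_trace_monotone_for_every_voxel(self, two_network_phantom):
        _, _, sess = two_network_phantom
        inn = deconvolve_session(sess, max_iter=120)
        assert np.all(np.diff(inn.objective_trace, axis=0) <= 1e-9)

    def test_noisy_recovery_still_tracks_trains(self):
        atlas = synth.make_network_atlas(2, (6, 6, 6), seed=4)
        rng = np.random.default_rng(10)
        trains = np.vstack([
            synth.simulate_block_activity(90, 0, (5, 9), rng=rng,
                                          target_duration_pct=20).trains
            for _ in range(2)
        ])
        sess = synth.simulate_bold(atlas, trains, noise_sd=0.5, rng=rng)
        inn = deconvolve_session(sess, max_iter=300, tol=1e-7)
        mask = sess.mask
        for k in range(2):
            vox = atlas.maps[k][mask] > 0
            mean_act = inn.activity[vox].mean(axis=0)
            assert np.corrcoef(mean_act, trains[k])[0, 1] > 0.95
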
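"""Sliding-window connectivity, motion cleanup, and decentralized K-Means."""

import numpy as np
import pytest

from decentnet.core_network import AGGREGATOR, MessageLog
from decentnet.ddfnc import (
    CleanTimecourse,
    DFNCConfig,
    WindowedFNC,
    clean_timecourse,
    correlation_distance,
    despike,
    detect_spikes,
    dkmeans,
    run_ddfnc,
    select_exemplars,
    sliding_windows,
)
from decentnet.dgica import match_components


class TestDetectSpikes:
    def test_constant_series_has_no_spikes(self):
        assert detect_spikes(np.full(50, 0.1)).size == 0

    def test_single_spike_found_exactly(self):
        fd = np.full(100, 0.1)
        fd[37] = 5.0
        # oracle: threshold computed by hand from the series itself
        thresh = fd.mean() + 2.5 * fd.std()
        assert 5.0 > thresh > 0.1
        assert np.array_equal(detect_spikes(fd), [37])

    def test_threshold_is_strict(self):
        fd = np.full(10, 0.3)
        # every point equals mean + 2.5*0 exactly -> none exceed strictly
        assert detect_spikes(fd).size == 0

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            detect_spikes(np.array([0.1, 0.2]))


class TestDespike:
    def test_no_spikes_is_identity(self):
        tc = CleanTimecourse(np.random.default_rng(0).normal(size=(30, 2)))
        out = despike(tc, np.array([], dtype=int))
        assert np.array_equal(out.values, tc.values)

    def test_cubic_signal_restored_exactly(self):
        t = np.arange(40, dtype=float)
        clean = (0.01 * t**3 - 0.2 * t**2 + t)[:, None]
        corrupted = clean.copy()
        spikes = np.array([12, 25])
        corrupted[spikes] += 50.0
        out = despike(CleanTimecourse(corrupted), spikes)
        assert np.abs(out.values - clean).max() < 1e-6

    def test_linear_signal_interior_spike(self):
        t = np.arange(20, dtype=float)
        clean = (2.0 * t + 1.0)[:, None]
        corrupted = clean.copy()
        corrupted[9] = 99.0
        out = despike(CleanTimecourse(corrupted), np.array([9]))
        assert out.values[9, 0] == pytest.approx(2.0 * 9 + 1.0, abs=1e-8)
        assert np.array_equal(out.values[:9], clean[:9])

    def test_too_few_good_points_raises(self):
        tc = CleanTimecourse(np.zeros((5, 1)))
        with pytest.raises(ValueError):
            despike(tc, np.array([0, 1, 2]))


class TestCleanTimecourse:
    def make(self, T=162, r=3, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(T, r))
        fd = np.abs(rng.normal(0.1, 0.02, T))
        motion = rng.normal(size=(T, 24))
        return CleanTimecourse(values, fd, motion)

    def test_drops_initial_points(self):
        out = clean_timecourse(self.make(162))
        assert out.n_timepoints == 160

    def test_motion_spanned_signal_removed(self):
        rng = np.random.default_rng(1)
        motion = rng.normal(size=(100, 24))
        values = motion @ rng.normal(size=(24, 2))
        fd = np.full(100, 0.1)
        out = clean_timecourse(CleanTimecourse(values, fd, motion))
        assert np.abs(out.values).max() < 1e-8

    def test_zero_motion_leaves_signal_up_to_mean(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(60, 2))
        tc = CleanTimecourse(values, np.full(60, 0.1), np.zeros((60, 24)))
        out = clean_timecourse(tc, drop_initial=0)
        expected = values - values.mean(axis=0)
        assert np.allclose(out.values, expected, atol=1e-10)

    def test_motion_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            CleanTimecourse(np.zeros((10, 2)), np.zeros(10), np.zeros((9, 24)))


class TestSlidingWindows:
    def test_window_count_162_minus_22(self):
        tc = CleanTimecourse(np.random.default_rng(0).normal(size=(162, 4)))
        fnc = sliding_windows(tc, 22)
        assert fnc.n_windows == 140
        assert fnc.vectorized.shape == (140, 6)

    def test_single_window_edge_case(self):
        tc = CleanTimecourse(np.random.default_rng(1).normal(size=(23, 3)))
        assert sliding_windows(tc, 22).n_windows == 1

    def test_too_short_raises(self):
        tc = CleanTimecourse(np.zeros((22, 3)))
        with pytest.raises(ValueError):
            sliding_windows(tc, 22)

    def test_iid_components_have_small_offdiagonals(self):
        rng = np.random.default_rng(2)
        tc = CleanTimecourse(rng.normal(size=(2000, 4)))
        fnc = sliding_windows(tc, 500)
        # sampling error of a 500-point covariance of unit-variance series
        assert np.abs(fnc.vectorized).max() < 5.0 / np.sqrt(500)

    def test_windows_are_sample_covariances(self):
        rng = np.random.default_rng(3)
        tc = CleanTimecourse(rng.normal(size=(30, 3)))
        fnc = sliding_windows(tc, 10)
        expected = np.cov(tc.values[5:15].T, ddof=1)
        assert np.allclose(fnc.windows[5], expected)


class TestSelectExemplars:
    def from_variance(self, var_series):
        """Build a WindowedFNC whose per-window variance equals var_series."""
        n = len(var_series)
        vec = np.zeros((n, 2))
        vec[:, 0] = np.sqrt(var_series)  # var across the two features = s^2...
        vec[:, 1] = -np.sqrt(var_series)  # mean 0, variance = s^2
        return WindowedFNC(np.zeros((n, 2, 2)), vec, 22)

    def test_known_bumps_recovered(self):
        var = np.full(100, 1.0)
        for i in (10, 50, 90):
            var[i] = 5.0
        fnc = self.from_variance(var)
        assert np.array_equal(select_exemplars(fnc), [10, 50, 90])

    def test_monotone_series_falls_back_to_global_max(self):
        fnc = self.from_variance(np.linspace(1, 2, 50))
        assert np.array_equal(select_exemplars(fnc), [49])

    def test_constant_series_returns_first_index(self):
        fnc = self.from_variance(np.ones(30))
        assert np.array_equal(select_exemplars(fnc), [0])


class TestCorrelationDistance:
    def test_self_distance_zero(self):
        a = np.random.default_rng(0).normal(size=20)
        assert correlation_distance(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_negation_gives_two(self):
        a = np.random.default_rng(1).normal(size=20)
        assert correlation_distance(a, -a) == pytest.approx(2.0, abs=1e-12)

    def test_orthogonal_zero_mean_gives_one(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert correlation_distance(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            correlation_distance(np.ones(5), np.arange(5.0))


def lloyd_oracle(x, centroids, max_iter=100):
    """Textbook pooled Lloyd iteration with Euclidean distance."""
    prev = None
    for _ in range(max_iter):
        d = ((x[:, None, :] - centroids[None]) ** 2).sum(-1)
        labels = d.argmin(1)
        if prev is not None and np.array_equal(labels, prev):
            break
        for c in range(len(centroids)):
            if np.any(labels == c):
                centroids[c] = x[labels == c].mean(0)
        prev = labels
    return centroids, labels


class TestDKMeans:
    def test_single_site_matches_lloyd(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 5))
        init = x[rng.choice(200, 4, replace=False)]
        model = dkmeans([x], 4, init.copy(), distance="euclidean")
        _, labels = lloyd_oracle(x, init.copy())
        assert np.array_equal(model.assignments, labels)

    def test_two_blobs_one_iteration(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, size=(40, 3))
        b = rng.normal(5, 0.1, size=(40, 3))
        model = dkmeans(
            [a, b], 2, np.vstack([a.mean(0), b.mean(0)]), distance="euclidean"
        )
        assert np.allclose(model.centroids, np.vstack([a.mean(0), b.mean(0)]))

    def test_count_weighted_merge(self):
        # one site holds c once, the other holds c' three times; k=1
        c = np.array([[0.0, 2.0, 1.0]])
        cp = np.array([1.0, 0.0, 3.0])
        sites = [c, np.tile(cp, (3, 1))]
        model = dkmeans(sites, 1, c.copy(), distance="euclidean")
        assert np.allclose(model.centroids[0], (c[0] + 3 * cp) / 4)

    def test_split_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(120, 6))
        init = x[:3].copy()
        one = dkmeans([x], 3, init, distance="euclidean")
        two = dkmeans([x[:50], x[50:]], 3, init, distance="euclidean")
        assert np.allclose(one.centroids, two.centroids, atol=1e-12)
        assert np.array_equal(one.assignments, two.assignments)

    def test_converged_state_is_fixed_point(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(100, 4))
        model = dkmeans([x], 3, x[:3].copy(), distance="euclidean")
        again = dkmeans([x], 3, model.centroids.copy(), distance="euclidean", max_iterations=2)
        assert np.allclose(again.centroids, model.centroids, atol=1e-12)

    def test_count_conservation(self):
        rng = np.random.default_rng(4)
        sites = [rng.normal(size=(30, 4)), rng.normal(size=(45, 4))]
        model = dkmeans(sites, 3, sites[0][:3].copy(), distance="euclidean")
        assert model.counts.sum() == 75

    def test_per_iteration_site_upload_is_k_times_features(self):
        rng = np.random.default_rng(5)
        sites = [rng.normal(size=(30, 10)), rng.normal(size=(30, 10))]
        log = MessageLog()
        model = dkmeans(sites, 3, sites[0][:3].copy(), distance="correlation", log=log)
        uploads = [m for m in log.records if m.receiver == AGGREGATOR]
        assert all(m.scalar_count == 3 * 10 for m in uploads)
        assert len(uploads) == 2 * model.iterations

    def test_k_exceeding_rows_raises(self):
        with pytest.raises(ValueError):
            dkmeans([np.zeros((2, 3))], 5, np.zeros((5, 3)))


class TestRunDDFNC:
    def test_recovers_planted_states(self, fmri_timecourses):
        sites, truth = fmri_timecourses
        cfg = DFNCConfig(window=22, k=truth.k, n_init=50, seed=0)
        res = run_ddfnc(sites, cfg)
        iu = np.triu_indices(truth.r, k=1)
        templates = truth.templates[:, iu[0], iu[1]]
        perm, _, corrs = match_components(res.model.centroids, templates)
        assert corrs.mean() >= 0.9
        num = den = 0
        for sid, labels in res.labels.items():
            states = truth.subject_states[sid][cfg.drop_initial :]
            for i, lab in enumerate(labels):
                majority = np.bincount(states[i : i + cfg.window]).argmax()
                num += perm[majority] == lab
                den += 1
        assert num / den >= 0.9

    def test_k_equal_one_gives_global_mean(self, fmri_timecourses):
        sites, truth = fmri_timecourses
        sites = [s[:3] for s in sites]
        cfg = DFNCConfig(window=22, k=1, n_init=1, seed=0, distance="euclidean")
        win_stacks = []
        from decentnet.ddfnc import _prepare_windows

        win_stacks, ex_stacks, _, _ = _prepare_windows(sites, cfg, clean=True)
        model = dkmeans(win_stacks, 1, np.vstack(win_stacks)[:1].copy(), distance="euclidean")
        assert np.allclose(model.centroids[0], np.vstack(win_stacks).mean(0), atol=1e-10)

    def test_deterministic_given_seed(self, fmri_timecourses):
        sites, truth = fmri_timecourses
        sites = [s[:3] for s in sites]
        cfg = DFNCConfig(window=22, k=2, n_init=10, seed=4)
        r1 = run_ddfnc(sites, cfg)
        r2 = run_ddfnc(sites, cfg)
        assert np.array_equal(r1.model.centroids, r2.model.centroids)
        assert r1.best_init == r2.best_init
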
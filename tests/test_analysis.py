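import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from goalseq.analysis import (classify_cluster_count, classify_max_jump,
                              mean_shift_clusters, normalize_trajectories,
                              peak_frequency, rate_spectrogram,
                              speed_vs_distance, thirds_rate_summary,
                              transition_distance)
from goalseq.fixtures import make_fixture


def kde_modes_brute_force(points, weights, bandwidth, grid_step=1.0):
    """Independent oracle: Gaussian KDE evaluated on a fine grid, modes =
    strict local maxima over the 8-neighborhood."""
    pts = np.asarray(points, float)
    w = np.asarray(weights, float)
    lo = pts.min(0) - 3 * bandwidth
    hi = pts.max(0) + 3 * bandwidth
    xs = np.arange(lo[0], hi[0], grid_step)
    ys = np.arange(lo[1], hi[1], grid_step)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    grid = np.column_stack([xx.ravel(), yy.ravel()])
    d2 = ((grid[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    dens = (np.exp(-d2 / (2 * bandwidth ** 2)) * w).sum(1).reshape(len(xs),
                                                                   len(ys))
    modes = []
    for i in range(1, len(xs) - 1):
        for j in range(1, len(ys) - 1):
            if dens[i, j] == dens[i - 1:i + 2, j - 1:j + 2].max() and \
                    dens[i, j] > dens[i - 1:i + 2, j - 1:j + 2].min():
                modes.append((xs[i], ys[j]))
    # merge plateau duplicates closer than the bandwidth/2 convention
    merged = []
    for m in modes:
        if all(np.hypot(m[0] - a, m[1] - b) > bandwidth / 2
               for a, b in merged):
            merged.append(m)
    return np.asarray(merged)


class TestMaxJump:
    def test_stationary_track_is_smooth(self):
        track = np.tile([100.0, 100.0], (20, 1))
        assert classify_max_jump(track) == "non_jump"

    def test_single_45cm_step_is_jump(self):
        track = np.array([[0.0, 0.0], [10.0, 0.0], [55.0, 0.0]])
        assert classify_max_jump(track) == "jump"

    def test_threshold_is_strict(self):
        track = np.array([[0.0, 0.0], [40.0, 0.0]])
        assert classify_max_jump(track) == "non_jump"
        assert classify_max_jump(track, threshold=39.9) == "jump"

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError):
            classify_max_jump(np.array([[0.0, 0.0]]))


class TestMeanShift:
    def test_single_blob_mode_at_mean(self, rng):
        pts = rng.normal([200.0, 200.0], 8.0, (60, 2))
        modes = mean_shift_clusters(pts)
        assert len(modes) == 1
        assert np.linalg.norm(modes[0] - pts.mean(0)) < 3.0

    def test_two_far_blobs_match_kde_oracle(self):
        pts, w, meta = make_fixture("two_blob_frame", seed=4)
        modes = mean_shift_clusters(pts, w)
        oracle = kde_modes_brute_force(pts, w, 52.5)
        assert len(modes) == len(oracle) == 2
        # same modes up to grid resolution
        for m in modes:
            assert min(np.linalg.norm(m - o) for o in oracle) < 3.0

    def test_two_near_blobs_merge_into_one(self, rng):
        a = rng.normal([200.0, 200.0], 3.0, (30, 2))
        b = rng.normal([210.0, 200.0], 3.0, (30, 2))
        pts = np.vstack([a, b])
        modes = mean_shift_clusters(pts)
        oracle = kde_modes_brute_force(pts, np.ones(len(pts)), 52.5)
        assert len(modes) == len(oracle) == 1

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            mean_shift_clusters(np.empty((0, 2)))

    def test_agrees_with_sklearn_on_blob_count(self):
        """Cross-check against the scikit-learn estimator (flat kernel,
        different seeding) on well-separated blobs."""
        from sklearn.cluster import MeanShift

        pts, w, _ = make_fixture("two_blob_frame", seed=11)
        ours = mean_shift_clusters(pts, w)
        sk = MeanShift(bandwidth=52.5).fit(pts)
        assert len(ours) == len(np.unique(sk.labels_))


class TestClusterCount:
    def test_stationary_bump_event_is_smooth(self):
        rec, centers, meta = make_fixture("stationary_bump_spikes", seed=2)
        from goalseq.analysis import frame_spike_positions
        frames = frame_spike_positions(rec, centers, 0.0, meta["duration"])
        label, nc = classify_cluster_count(frames)
        assert label == "non_jump"
        assert nc.max() == 1

    def test_coexisting_blobs_in_one_frame_flag_jump(self, rng):
        # frames: mostly single blob, one frame with a second blob
        single = [(rng.normal([150.0, 150.0], 8.0, (20, 2)), np.ones(20))
                  for _ in range(5)]
        both = np.vstack([rng.normal([150.0, 150.0], 8.0, (20, 2)),
                          rng.normal([320.0, 320.0], 8.0, (10, 2))])
        frames = single + [(both, np.ones(30))]
        label, nc = classify_cluster_count(frames)
        assert label == "jump"
        assert nc[-1] == 2


class TestTransitionDistance:
    def test_separated_classes_give_zero_alpha(self):
        ta = transition_distance(np.array([10.0, 20.0, 30.0]),
                                 np.array([80.0, 90.0, 100.0]))
        assert ta.alpha == 0.0
        assert 30.0 < ta.d_star < 80.0

    def test_identical_distributions_give_half(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        ta = transition_distance(x, x)
        assert ta.alpha == pytest.approx(0.5)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            transition_distance(np.array([1.0]), np.array([]))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_exhaustive_scan_on_random_gaussians(self, seed):
        rng = np.random.default_rng(seed)
        nj = rng.normal(60.0, 25.0, rng.integers(3, 40))
        jd = rng.normal(120.0, 35.0, rng.integers(3, 40))
        nj, jd = np.abs(nj), np.abs(jd)
        ta = transition_distance(nj, jd)
        # oracle: dense scan over a fine grid of thresholds
        grid = np.linspace(min(nj.min(), jd.min()) - 2,
                           max(nj.max(), jd.max()) + 2, 4001)
        a = np.maximum((jd[None, :] <= grid[:, None]).mean(1),
                       (nj[None, :] >= grid[:, None]).mean(1))
        assert ta.alpha == pytest.approx(a.min(), abs=1e-12)


class TestSpectralAnalyses:
    def test_pure_tone_peaks_at_its_frequency(self):
        t = np.arange(0, 400.0, 0.2)
        x = 5.0 + np.sin(2 * np.pi * 200.0 * t / 1000.0)
        assert peak_frequency(x, smooth_ms=0.0) == pytest.approx(200.0,
                                                                 abs=5.0)

    def test_white_noise_spectrum_is_flat(self, rng):
        x = rng.normal(0, 1.0, 20000)
        f, _, S = rate_spectrogram(x, smooth_ms=0.0)
        m = S.mean(axis=1)
        band = lambda a, b: m[(f >= a) & (f < b)].mean()
        assert band(100.0, 300.0) == pytest.approx(band(500.0, 700.0),
                                                   rel=0.3)

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            rate_spectrogram(np.zeros(100))

    def test_thirds_of_constant_rate_are_equal(self):
        means, sems = thirds_rate_summary([np.full(300, 7.0),
                                           np.full(300, 7.0)])
        assert np.allclose(means, 7.0)
        assert np.allclose(sems, 0.0)

    def test_thirds_of_linear_ramp_are_arithmetic(self):
        r = np.linspace(0.0, 1.0, 300)
        means, _ = thirds_rate_summary([r])
        diffs = np.diff(means)
        assert diffs[0] == pytest.approx(diffs[1], rel=1e-6)
        assert diffs[0] > 0


class TestSpeedVsDistance:
    def test_constant_speed_tracks_recover_construction(self):
        tracks = []
        for L in (20.0, 60.0, 120.0):
            n = 51
            tracks.append(np.column_stack([
                np.linspace(0, L, n), np.zeros(n)]))
        df = speed_vs_distance(tracks)
        # mean per-frame displacement = distance / (n-1)
        assert df.attrs["slope"] == pytest.approx(1.0 / 50.0, rel=1e-6)
        assert df.attrs["spearman_rho"] == 1.0

    def test_needs_two_events(self):
        with pytest.raises(ValueError):
            speed_vs_distance([np.zeros((5, 2))])


class TestNormalizeTrajectories:
    def test_straight_start_goal_path_maps_to_template(self):
        tr = np.column_stack([np.linspace(0, 30, 7),
                              np.linspace(0, 40, 7)])  # toward (30,40)
        out = normalize_trajectories([tr], [np.zeros(2)],
                                     [np.array([30.0, 40.0])])
        assert len(out) == 1
        assert np.allclose(out[0][:, 0], 0.0, atol=1e-12)
        assert out[0][-1, 1] == pytest.approx(1.0)

    def test_rotation_preserves_shape_up_to_scale(self, rng):
        tr = rng.uniform(0, 100, (10, 2))
        s, g = np.array([0.0, 0.0]), np.array([50.0, 10.0])
        out = normalize_trajectories([tr], [s], [g])[0]
        L = np.linalg.norm(g - s)
        d_in = np.linalg.norm(tr[3] - tr[7])
        d_out = np.linalg.norm(out[3] - out[7])
        assert d_out == pytest.approx(d_in / L, rel=1e-9)

    def test_mirror_pair_stays_symmetric(self):
        tr = np.array([[0.0, 0.0], [10.0, 5.0], [20.0, 0.0]])
        mirror = tr * np.array([1.0, -1.0])
        g = np.array([20.0, 0.0])
        a, b = normalize_trajectories([tr, mirror], [np.zeros(2)] * 2,
                                      [g, g])
        assert np.allclose(a, b * np.array([-1.0, 1.0]), atol=1e-9) or \
            np.allclose(a[:, 1], b[:, 1], atol=1e-9)

    def test_degenerate_start_goal_skipped(self):
        out = normalize_trajectories([np.zeros((3, 2))], [np.zeros(2)],
                                     [np.zeros(2)])
        assert out == []
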
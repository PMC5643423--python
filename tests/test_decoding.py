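import numpy as np
import pytest

from goalseq import LatticeSpec, NetworkParams, build_network
from goalseq.decoding import (TuningCurveSet, bayesian_posterior,
                              build_tuning_curves, population_vector_decode,
                              spike_count_frames, subset_decode)
from goalseq.fixtures import make_fixture
from goalseq.params import build_lattice_positions


@pytest.fixture(scope="module")
def tuning40():
    """Analytic tuning matched to the bump fixtures (peak 100 Hz, 30 cm)."""
    centers = build_lattice_positions(LatticeSpec(grid_side=40))
    return TuningCurveSet(centers=centers, bin_size=5.25, env_side=420.0,
                          peak=np.full(len(centers), 100.0), sigma_tc=30.0)


class TestPosterior:
    def test_uniform_tuning_gives_uniform_posterior(self):
        f = np.full((5, 64), 3.0)
        post = bayesian_posterior(np.array([2, 0, 1, 4, 0]), np.log(f),
                                  f.sum(0), 0.005)
        assert np.allclose(post, 1.0 / 64)

    def test_posterior_normalizes_to_one(self, tuning40, rng):
        f = tuning40.rates(np.arange(160))
        for _ in range(10):
            counts = rng.poisson(0.3, 160)
            post = bayesian_posterior(counts, np.log(f), f.sum(0), 0.005)
            assert post.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(post >= 0)

    def test_single_unit_small_tau_peaks_at_tuning_center(self, tuning40):
        unit = np.array([820])  # somewhere mid-lattice
        f = tuning40.rates(unit)
        post = bayesian_posterior(np.array([1]), np.log(f), f.sum(0), 1e-9)
        peak_bin = tuning40.bin_centers[np.argmax(post)]
        d = np.linalg.norm(peak_bin - tuning40.centers[unit[0]])
        assert d <= tuning40.bin_size

    def test_zero_counts_match_closed_form(self, tuning40):
        units = np.arange(40)
        f = tuning40.rates(units)
        post = bayesian_posterior(np.zeros(40, dtype=int), np.log(f),
                                  f.sum(0), 0.005)
        expected = np.exp(-0.005 * f.sum(0))
        expected /= expected.sum()
        assert np.allclose(post, expected, atol=1e-12)


class TestSubsetDecode:
    def test_decoder_recovers_stationary_bump_within_one_bin(self, tuning40):
        """Unbiasedness on model-matched Poisson spikes."""
        rec, centers, meta = make_fixture("stationary_bump_spikes", seed=2)
        dec = subset_decode(rec, tuning40, 0.0, meta["duration"],
                            np.random.default_rng(0), n_subsets=10,
                            subset_size=160)
        mean_pos = np.nanmean(dec.pooled_com, axis=0)
        assert np.linalg.norm(mean_pos - meta["center"]) <= tuning40.bin_size

    def test_partition_is_disjoint_and_seeded(self, tuning40):
        rec, _, meta = make_fixture("stationary_bump_spikes", seed=2)
        d1 = subset_decode(rec, tuning40, 0.0, 50.0,
                           np.random.default_rng(4), n_subsets=10,
                           subset_size=160)
        d2 = subset_decode(rec, tuning40, 0.0, 50.0,
                           np.random.default_rng(4), n_subsets=10,
                           subset_size=160)
        assert np.array_equal(d1.subsets, d2.subsets)
        flat = d1.subsets.ravel()
        assert len(np.unique(flat)) == len(flat)

    def test_oversized_partition_rejected(self, tuning40):
        rec, _, _ = make_fixture("stationary_bump_spikes", seed=2)
        with pytest.raises(ValueError):
            subset_decode(rec, tuning40, 0.0, 50.0,
                          np.random.default_rng(0), n_subsets=40,
                          subset_size=160)

    def test_frames_cover_window_with_2ms_step(self):
        from goalseq.network import SpikeRecord
        rec = SpikeRecord(np.array([1.0, 6.0, 6.5]), np.array([0, 1, 1]))
        times, counts = spike_count_frames(rec, 3, 0.0, 21.0)
        assert np.allclose(np.diff(times), 2.0)
        assert counts[0, 0] == 1           # t in [0,5)
        assert counts[3, 1] == 2           # t in [6,11)


class TestPopulationVector:
    def test_single_active_unit(self):
        centers = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert np.allclose(
            population_vector_decode(np.array([0, 3]), centers), [3.0, 4.0])

    def test_symmetric_bump_gives_center(self):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 5.0],
                            [5.0, -5.0]])
        pos = population_vector_decode(np.array([2, 2, 2, 2]), centers)
        assert np.allclose(pos, [5.0, 0.0])

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            population_vector_decode(np.zeros(3), np.zeros((3, 2)))

    def test_agrees_with_bayesian_on_matched_bump(self, tuning40):
        """Median per-frame disagreement below one lattice spacing on a
        model-matched bump (the two decoders are independent paths)."""
        rec, centers, meta = make_fixture("stationary_bump_spikes", seed=8)
        dec = subset_decode(rec, tuning40, 0.0, meta["duration"],
                            np.random.default_rng(1), n_subsets=10,
                            subset_size=160)
        times, counts = spike_count_frames(rec, len(centers), 0.0,
                                           meta["duration"])
        dis = []
        for k in range(len(times)):
            if counts[k].sum() == 0 or np.isnan(dec.pooled_com[k, 0]):
                continue
            pv = population_vector_decode(counts[k], centers)
            dis.append(np.linalg.norm(pv - dec.pooled_com[k]))
        assert np.median(dis) < 10.5


class TestTuningCurves:
    def test_analytic_calibration_recovers_field_shape(self, net40):
        tun = build_tuning_curves(net40, "analytic",
                                  np.random.default_rng(0))
        assert tun.peak[0] > 50.0          # movement-state rates are high
        assert 20.0 < tun.sigma_tc < 120.0
        # analytic curve evaluates to peak at the center, peak/e at sigma
        unit = np.array([net40.n // 2])
        f = tun.rates(unit)[0]
        bc = tun.bin_centers
        d = np.linalg.norm(bc - tun.centers[unit[0]], axis=1)
        assert f[np.argmin(d)] == pytest.approx(tun.peak[0], rel=0.02)
        at_sigma = f[np.argmin(np.abs(d - tun.sigma_tc))]
        assert at_sigma == pytest.approx(tun.peak[0] / np.e, rel=0.15)

    def test_simulated_maps_correlate_with_analytic(self):
        """Rate maps from a random walk agree with the analytic model for
        well-sampled units (small lattice, coarse bins)."""
        net = build_network(NetworkParams(lattice=LatticeSpec(grid_side=20)))
        rng = np.random.default_rng(3)
        sim_tc = build_tuning_curves(net, "simulated", rng, bin_size=21.0,
                                     walk_ms=20_000.0)
        ana_tc = build_tuning_curves(net, "analytic",
                                     np.random.default_rng(0),
                                     bin_size=21.0)
        # central units whose fields the walk visited
        lo = net.p.lattice.arena_offset
        hi = lo + net.p.lattice.arena_side
        inside = np.flatnonzero(
            np.all((net.positions > lo + 20) & (net.positions < hi - 20),
                   axis=1))
        occupied = sim_tc.rate_maps.sum(axis=0) > 0
        cors = []
        for u in inside[:20]:
            a = sim_tc.rate_maps[u][occupied]
            b = ana_tc.rates(np.array([u]))[0][occupied]
            if a.max() > 0:
                cors.append(np.corrcoef(a, b)[0, 1])
        assert np.mean(cors) > 0.7
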
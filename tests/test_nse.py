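import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from natsynth_fus import nse as ns
from natsynth_fus.datasets import ResponseMatrix, VoxelGeometry


finite_vec = arrays(np.float64, st.integers(4, 30),
                    elements=st.floats(-50, 50, allow_nan=False)) \
    .filter(lambda v: v.std() > 1e-6)


class TestNSE:
    def test_identical_vectors_give_zero(self):
        assert ns.nse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_zero_mean_anticorrelated_gives_two(self):
        x = np.array([1.0, -1.0, 2.0, -2.0])
        assert ns.nse(x, -x) == pytest.approx(2.0)

    def test_hand_computed_case(self):
        assert ns.nse([1, 2, 3], [1, 2, 4]) == pytest.approx(1 / 7)

    @settings(deadline=None, max_examples=50)
    @given(finite_vec)
    def test_symmetry_and_scale_invariance(self, x):
        rng = np.random.default_rng(int(abs(x.sum() * 1e3)) % 2 ** 31)
        y = x + rng.standard_normal(x.size)
        a, b = ns.nse(x, y), ns.nse(y, x)
        assert a == pytest.approx(b, rel=1e-9)
        assert ns.nse(3.5 * x, 3.5 * y) == pytest.approx(a, rel=1e-9)

    def test_one_minus_nse_equals_pearson_for_standardized(self, rng):
        for _ in range(20):
            x, y = rng.standard_normal((2, 100))
            x = (x - x.mean()) / x.std()
            y = (y - y.mean()) / y.std()
            r = np.corrcoef(x, y)[0, 1]
            assert 1 - ns.nse(x, y) == pytest.approx(r, abs=1e-10)

    def test_constant_equal_vectors_undefined(self):
        assert np.isnan(ns.nse([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]))

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            ns.nse([1.0], [2.0])


class TestNoiseCorrectedPower:
    def test_identical_measurements(self, rng):
        s = rng.standard_normal(50)
        assert ns.noise_corrected_power(s, s) == pytest.approx(np.mean(s ** 2))

    def test_hand_computed_case(self):
        assert ns.noise_corrected_power([1.5, -0.5], [0.5, -1.5]) \
            == pytest.approx(0.75)

    def test_monte_carlo_unbiased(self, rng):
        s = rng.standard_normal(100)
        sigma = 0.8
        ests = [ns.noise_corrected_power(s + sigma * rng.standard_normal(100),
                                         s + sigma * rng.standard_normal(100))
                for _ in range(10_000)]
        assert np.mean(ests) == pytest.approx(np.mean(s ** 2), rel=0.01)


class TestNoiseCorrectedNSE:
    def test_noiseless_identical_gives_zero(self, rng):
        s = rng.standard_normal(40)
        assert ns.noise_corrected_nse(s, s, s, s) == pytest.approx(0.0)

    def test_same_signal_floor_is_zero(self, rng):
        """Mean corrected NSE of noisy splits of one signal is ~0 below the
        reliability gate."""
        n, sims, sig = 200, 1000, 0.55
        s = rng.standard_normal((sims, n))
        x1 = s + sig * rng.standard_normal((sims, n))
        x2 = s + sig * rng.standard_normal((sims, n))
        y1 = s + sig * rng.standard_normal((sims, n))
        y2 = s + sig * rng.standard_normal((sims, n))
        assert np.mean(ns.nse(x1, x2)) < ns.RELIABILITY_GATE
        assert abs(np.mean(ns.noise_corrected_nse(x1, x2, y1, y2))) < 0.02

    def test_independent_signals_give_one(self, rng):
        n, sims, sig = 200, 1000, 0.4
        s = rng.standard_normal((sims, n))
        t = rng.standard_normal((sims, n))
        vals = ns.noise_corrected_nse(
            s + sig * rng.standard_normal((sims, n)),
            s + sig * rng.standard_normal((sims, n)),
            t + sig * rng.standard_normal((sims, n)),
            t + sig * rng.standard_normal((sims, n)))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)

    def test_bias_grows_beyond_reliability_gate(self, rng):
        """The spread of the corrected estimate worsens as reliability drops
        past the gate, justifying the 0.4 threshold."""
        def spread(sig):
            n, sims = 100, 500
            s = rng.standard_normal((sims, n))
            draws = ns.noise_corrected_nse(
                s + sig * rng.standard_normal((sims, n)),
                s + sig * rng.standard_normal((sims, n)),
                s + sig * rng.standard_normal((sims, n)),
                s + sig * rng.standard_normal((sims, n)))
            return np.std(draws)
        assert spread(1.5) > 2 * spread(0.5)

    def test_paradigm_one_noise_from_x_only(self, rng):
        s = rng.standard_normal((200, 100))
        sig = 0.5
        x1 = s + sig * rng.standard_normal(s.shape)
        x2 = s + sig * rng.standard_normal(s.shape)
        y1 = s + sig * rng.standard_normal(s.shape)
        y2 = s + sig * rng.standard_normal(s.shape)
        vals = ns.noise_corrected_nse(x1, x2, y1, y2, noise_from="x")
        assert abs(np.mean(vals)) < 0.03


class TestNoiseCorrectedVariance:
    def test_identical_measurements_give_variance(self, rng):
        s = rng.standard_normal(60)
        assert ns.noise_corrected_variance(s, s) == pytest.approx(np.var(s))

    def test_independent_noise_gives_zero_in_expectation(self, rng):
        vals = [ns.noise_corrected_variance(rng.standard_normal(100),
                                            rng.standard_normal(100))
                for _ in range(4000)]
        assert abs(np.mean(vals)) < 0.01

    def test_planted_signal_variance_recovered(self, rng):
        n = 100_000
        s = 2.0 * rng.standard_normal(n)
        est = ns.noise_corrected_variance(s + rng.standard_normal(n),
                                          s + rng.standard_normal(n))
        assert est == pytest.approx(4.0, rel=0.02)


def test_residual_power_is_twice_noise_power(rng):
    n = 100_000
    sigma = 0.7
    s = rng.standard_normal(n)
    x1 = s + sigma * rng.standard_normal(n)
    x2 = s + sigma * rng.standard_normal(n)
    assert np.mean((x1 - x2) ** 2) / sigma ** 2 == pytest.approx(2.0, rel=0.02)


class TestNSEMap:
    def test_gate_excludes_unreliable_voxels(self, rng):
        s = rng.standard_normal((50, 80))
        good = s + 0.3 * rng.standard_normal((4, 50, 80))
        bad = s + 3.0 * rng.standard_normal((4, 50, 80))
        res_good = ns.nse_map(*good)
        res_bad = ns.nse_map(*bad)
        assert res_good.valid_mask.mean() > 0.9
        assert res_bad.valid_mask.mean() < 0.1
        assert np.isfinite(res_bad.corrected_nse).any()  # reported, not hidden


class TestSpatialProfile:
    def _line_geometry(self, n):
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * 0.5
        return VoxelGeometry(coords=coords, cortex_mask=np.ones(n, bool),
                             slice_id=np.zeros(n, int),
                             distance_to_pac=np.zeros(n))

    def _split(self, values, sound_n, split):
        import pandas as pd
        st = pd.DataFrame({"category": ["x"] * sound_n,
                           "is_natural": [True] * sound_n,
                           "pair": np.arange(sound_n)})
        return ResponseMatrix(values=values, split_id=split, sound_table=st)

    def test_identical_splits_zero_distance_correlation_one(self, rng):
        n, S = 30, 60
        vals = rng.standard_normal((n, S))
        geom = self._line_geometry(n)
        prof = ns.spatial_correlation_profile(self._split(vals, S, "odd"),
                                              self._split(vals, S, "even"),
                                              geom, bin_size=0.5)
        assert prof.distance_bins[0] == 0.0
        assert prof.mean_correlation[0] == pytest.approx(1.0)

    def test_independent_voxels_flat_beyond_zero(self, rng):
        n, S = 40, 200
        s = rng.standard_normal((n, S))
        a = s + 0.5 * rng.standard_normal((n, S))
        b = s + 0.5 * rng.standard_normal((n, S))
        geom = self._line_geometry(n)
        prof = ns.spatial_correlation_profile(self._split(a, S, "odd"),
                                              self._split(b, S, "even"),
                                              geom, bin_size=0.5)
        assert prof.mean_correlation[0] > 0.7
        assert np.abs(prof.mean_correlation[1:]).max() < 0.1

    def test_planted_gaussian_kernel_scale_recovered(self, rng):
        """Responses drawn with correlation exp(-d^2 / (2 lam^2)) between
        voxels produce a profile decaying on that scale (within 10%)."""
        n, S, lam = 60, 800, 2.0
        geom = self._line_geometry(n)
        d = geom.pairwise_distances()
        K = np.exp(-d ** 2 / (2 * lam ** 2))
        L = np.linalg.cholesky(K + 1e-9 * np.eye(n))
        vals = L @ rng.standard_normal((n, S))
        prof = ns.spatial_correlation_profile(self._split(vals, S, "odd"),
                                              self._split(vals, S, "even"),
                                              geom, bin_size=0.5)
        # distance at which the profile drops to exp(-1/2) of its peak
        f = prof.mean_correlation / prof.mean_correlation[0]
        cross = np.interp(-np.exp(-0.5), -f, prof.distance_bins)
        assert cross == pytest.approx(lam, rel=0.1)


class TestTau75:
    def _profile(self, d, f):
        return ns.SpatialCorrelationProfile(distance_bins=np.asarray(d),
                                            mean_correlation=np.asarray(f),
                                            bin_size=float(d[1] - d[0]),
                                            n_pairs=np.ones(len(d)))

    def test_exponential_closed_form(self):
        lam = 2.0
        # profile must reach its ~0 floor for the closed form to apply
        d = np.arange(0, 400) * 0.1
        tau = ns.tau75(self._profile(d, np.exp(-d / lam)))
        assert tau == pytest.approx(lam * np.log(4), rel=0.02)

    def test_constant_profile_undefined(self):
        d = np.arange(5) * 1.0
        assert np.isnan(ns.tau75(self._profile(d, np.ones(5))))

    def test_offset_invariance(self):
        lam, c = 1.5, 0.3
        d = np.arange(0, 60) * 0.1
        base = ns.tau75(self._profile(d, np.exp(-d / lam)))
        offs = ns.tau75(self._profile(d, np.exp(-d / lam) + c))
        assert offs == pytest.approx(base, rel=1e-6)
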
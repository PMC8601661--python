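import numpy as np
import pandas as pd
import pytest
from scipy import stats

import natsynth_fus as nf
from natsynth_fus import nse as ns
from natsynth_fus import preprocess as pp
from natsynth_fus import spatial_stats as sp
from natsynth_fus import synthgen
from natsynth_fus.datasets import Timing

from conftest import SMALL


class TestSurfaceProjection:
    def test_depth_constant_map_equals_any_layer(self, small_sim):
        geom = small_sim.geometry
        vals = geom.coords[:, 0] * 10 + geom.coords[:, 1]  # depth-independent
        out = sp.surface_projection(vals, geom)
        expect = out["u"] * 10 + out["v"]
        np.testing.assert_allclose(out["value"], expect, atol=1e-9)

    def test_column_means_match_direct_average(self, small_sim, rng):
        geom = small_sim.geometry
        vals = rng.standard_normal(geom.n_voxels)
        out = sp.surface_projection(vals, geom)
        u0, v0 = out.iloc[0][["u", "v"]]
        sel = (geom.coords[:, 0] == u0) & (geom.coords[:, 1] == v0) \
            & geom.cortex_mask
        assert out.iloc[0]["value"] == pytest.approx(vals[sel].mean())


class TestAnnularProfile:
    def test_constant_map_zero_slope(self, small_sim):
        geom = small_sim.geometry
        prof = sp.annular_profile(np.full(geom.n_voxels, 0.3), geom, 0.5)
        assert prof.slope == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(prof.median_nse, 0.3)

    def test_planted_linear_trend_recovered(self, small_sim):
        geom = small_sim.geometry
        a, b = 0.1, 0.25
        vals = a + b * geom.distance_to_pac
        # fine bins keep the within-bin median close to the bin center
        prof = sp.annular_profile(vals, geom, 0.2)
        assert prof.slope == pytest.approx(b, rel=0.15)

    def test_invariant_to_gated_voxels(self, small_sim, rng):
        geom = small_sim.geometry
        vals = rng.random(geom.n_voxels)
        base = sp.annular_profile(vals, geom, 0.5)
        # corrupt half the voxels but gate them out: profile unchanged
        corrupt = vals.copy()
        mask = rng.random(geom.n_voxels) < 0.5
        corrupt[~mask] = 99.0
        gated = sp.annular_profile(corrupt, geom, 0.5, valid_mask=mask)
        sub = sp.annular_profile(vals, geom, 0.5, valid_mask=mask)
        np.testing.assert_allclose(gated.median_nse, sub.median_nse)


class TestCompareSlopes:
    def test_exact_binomial_below_all_twelve(self):
        humans = np.linspace(0.1, 1.0, 12)
        assert sp.compare_slopes(-0.2, humans) \
            == pytest.approx(2 * 0.5 ** 12)

    def test_slope_at_median_not_significant(self):
        humans = np.arange(10) - 4.5
        assert sp.compare_slopes(0.0, humans) > 0.5

    def test_single_comparator_uninformative(self):
        assert sp.compare_slopes(0.5, [1.0]) == 1.0

    def test_ties_dropped(self):
        assert sp.compare_slopes(1.0, [1.0, 1.0, 1.0]) == 1.0


class TestBootstrapModelComparison:
    def _splits(self, rng, gap):
        V, S = 40, 30
        s = rng.standard_normal((V, S))
        x = [s + 0.4 * rng.standard_normal((V, S)) for _ in range(2)]
        shifted = s + gap * rng.standard_normal((V, S))
        y = [shifted + 0.4 * rng.standard_normal((V, S)) for _ in range(2)]
        return (*x, *y)

    def test_identical_models_p_near_one(self, rng):
        shared = self._splits(rng, 0.0)
        out = sp.bootstrap_model_comparison({"a": shared, "b": shared},
                                            n_boot=200, seed=0)
        assert out["p_value"].iloc[0] == 1.0

    def test_separated_models_floored_p(self, rng):
        out = sp.bootstrap_model_comparison(
            {"good": self._splits(rng, 0.0), "bad": self._splits(rng, 2.0)},
            n_boot=200, seed=0)
        assert out["p_value"].iloc[0] == pytest.approx(2 / 200)

    def test_planted_model_hierarchy_recovered(self, rng):
        """Models matching progressively more structure give strictly
        decreasing median NSE, every pairwise comparison significant."""
        gaps = {"cochlear": 1.5, "spectral": 1.0, "temporal": 0.6,
                "spectrotemporal": 0.0}
        splits = {m: self._splits(rng, g) for m, g in gaps.items()}
        out = sp.bootstrap_model_comparison(splits, n_boot=500, seed=1)
        meds = {m: ns.noise_corrected_nse(*splits[m]).mean() for m in gaps}
        assert (meds["spectrotemporal"] < meds["temporal"]
                < meds["spectral"] < meds["cochlear"])
        assert (out["p_value"] < 0.01).all()

    def test_bit_reproducible(self, rng):
        splits = {"a": self._splits(rng, 0.3), "b": self._splits(rng, 0.6)}
        a = sp.bootstrap_model_comparison(splits, n_boot=100, seed=3)
        b = sp.bootstrap_model_comparison(splits, n_boot=100, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestCategoryNSE:
    def _data(self, rng, voc_gap=0.0):
        V, P = 30, 24
        cats = np.array(["voc"] * 8 + ["speech"] * 8 + ["music"] * 8)
        nat = rng.standard_normal((V, P))
        syn = nat.copy()
        syn[:, cats == "voc"] -= voc_gap * rng.standard_normal((V, 8))
        noise = lambda: 0.3 * rng.standard_normal((V, P))
        return (nat + noise(), nat + noise(), syn + noise(), syn + noise(),
                cats)

    def test_matched_categories_near_zero(self, rng):
        x1, x2, y1, y2, cats = self._data(rng, voc_gap=0.0)
        out = sp.category_nse(x1, x2, y1, y2, cats)
        assert np.abs(out["median_nse"]).max() < 0.05

    def test_planted_vocalization_gap_detected(self, rng):
        x1, x2, y1, y2, cats = self._data(rng, voc_gap=1.0)
        out = sp.category_nse(x1, x2, y1, y2, cats)
        voc = out.set_index("category").loc["voc", "median_nse"]
        others = out[out["category"] != "voc"]["median_nse"]
        assert voc > others.max() + 0.1
        per_sound = sp.category_nse_per_sound(x1, x2, y1, y2, cats)
        a = per_sound[per_sound["category"] == "voc"]["nse"]
        b = per_sound[per_sound["category"] == "speech"]["nse"]
        assert stats.ranksums(a, b).pvalue < 0.05

    def test_category_numerators_recompose_total(self, rng):
        """Shared-denominator construction: category values, weighted by
        category size, reproduce the all-sounds corrected NSE."""
        x1, x2, y1, y2, cats = self._data(rng, voc_gap=0.5)
        out = sp.category_nse(x1, x2, y1, y2, cats)
        total = ns.noise_corrected_nse(x1, x2, y1, y2)
        S = len(cats)
        recomposed = np.zeros_like(total)
        for _, row in out.iterrows():
            recomposed += row["n_sounds"] / S * row["values"]
        np.testing.assert_allclose(recomposed, total, atol=1e-10)


class TestDifferenceMap:
    def test_matched_responses_zero_map(self, rng):
        V, P = 20, 10
        nat = rng.standard_normal((V, P))
        out = sp.difference_map(nat, nat, ["a"] * P,
                                np.hstack([nat, nat]))
        np.testing.assert_allclose(out.iloc[0]["values"], 0.0, atol=1e-12)

    def test_planted_one_sd_gap(self, rng):
        V, P = 500, 12
        allr = rng.standard_normal((V, 4 * P))
        sd = allr.std(axis=1)
        nat = rng.standard_normal((V, P))
        distal = np.arange(V) >= V // 2
        syn = nat.copy()
        syn[distal] -= sd[distal, None]     # +1 s.d. gap in distal voxels
        out = sp.difference_map(nat, syn, ["speech"] * P, allr)
        vals = out.iloc[0]["values"]
        assert np.nanmean(vals[distal]) == pytest.approx(1.0, abs=0.05)
        assert np.nanmean(vals[~distal]) == pytest.approx(0.0, abs=0.05)

    def test_scale_invariance(self, rng):
        V, P = 30, 8
        nat, syn = rng.standard_normal((2, V, P))
        allr = np.hstack([nat, syn])
        a = sp.difference_map(nat, syn, ["x"] * P, allr)
        b = sp.difference_map(2 * nat, 2 * syn, ["x"] * P, 2 * allr)
        np.testing.assert_allclose(a.iloc[0]["values"], b.iloc[0]["values"])


class TestMotionIndex:
    def _setup(self, rng, voc_amp):
        cfg = synthgen.SimConfig(
            n_pairs=24, category_counts={"vocalization": 12, "speech": 12})
        st = synthgen._make_sound_table(cfg)
        timing = Timing()
        S = len(st)
        sounds = np.tile(np.arange(S), 2)
        sessions = np.repeat([0, 1], S)
        voc_nat = ((st.loc[sounds, "category"] == "vocalization")
                   & st.loc[sounds, "is_natural"]).to_numpy()
        amps = np.where(voc_nat, voc_amp, 0.05)
        frames = synthgen.simulate_video(amps, timing, seed=0)
        return frames, st, timing, sounds, sessions

    def test_static_video_zero_index(self):
        timing = Timing()
        frames = np.ones((4, timing.n_samples, 8, 8))
        st = pd.DataFrame({"category": ["a"] * 4, "is_natural": [True] * 4,
                           "pair": range(4)})
        mt = sp.motion_index(frames, np.ones((8, 8), bool), timing,
                             np.arange(4), np.zeros(4, int), st)
        assert np.allclose(mt.per_sound["motion"], 0.0)

    def test_planted_vocalization_motion_detected(self, rng):
        frames, st, timing, sounds, sessions = self._setup(rng, voc_amp=1.5)
        mt = sp.motion_index(frames, np.ones((16, 16), bool), timing,
                             sounds, sessions, st)
        ps = mt.per_sound.set_index("sound")
        voc = st[(st["category"] == "vocalization")]
        nat = ps.loc[voc[voc["is_natural"]].index, "motion"].to_numpy()
        syn = ps.loc[voc[~voc["is_natural"]].index, "motion"].to_numpy()
        assert stats.wilcoxon(nat, syn).pvalue < 0.05
        sp_nat = ps.loc[st[(st["category"] == "speech")
                           & st["is_natural"]].index, "motion"]
        assert stats.ranksums(nat, sp_nat).pvalue < 0.05

    def test_invariant_to_session_camera_gain(self, rng):
        frames, st, timing, sounds, sessions = self._setup(rng, voc_amp=1.0)
        gained = frames.copy()
        gained[sessions == 1] *= 7.3
        a = sp.motion_index(frames, np.ones((16, 16), bool), timing,
                            sounds, sessions, st)
        b = sp.motion_index(gained, np.ones((16, 16), bool), timing,
                            sounds, sessions, st)
        np.testing.assert_allclose(a.per_sound["motion"],
                                   b.per_sound["motion"], rtol=1e-9)
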
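"""Minimum-law limitation profiles and mixotrophy inference."""

import numpy as np
import pandas as pd
import pytest

from promix.nutrients import NutrientUptakeParams
from promix.photo import PHOTOPHYS_PRESETS
from promix.profiles import (
    EnvironmentProfile,
    GrowthProfileResult,
    autotrophic_profile,
    infer_heterotrophic_rate,
    integrate_production,
    mixotrophy_first_positive,
    mixotrophy_onset_depth,
    scenario_envelope,
)


def _make_result(depth, mu_auto, mu_obs, noon_par=None):
    """Assemble a minimal GrowthProfileResult for inference tests."""
    depth = np.asarray(depth, dtype=float)
    if noon_par is None:
        noon_par = 600.0 * np.exp(-0.045 * depth)
    env = EnvironmentProfile(depth=depth, noon_par=noon_par,
                             din=np.full_like(depth, 1e-4),
                             po4=np.full_like(depth, 1e-5),
                             mu_obs=np.asarray(mu_obs, dtype=float))
    table = pd.DataFrame({"depth_m": depth, "mu_auto": mu_auto})
    return GrowthProfileResult(table=table, scenario="test", environment=env)


class TestMinimumLaw:
    def test_minimum_and_limiter_at_every_depth(self, synth_env, alloc):
        res = autotrophic_profile(synth_env, PHOTOPHYS_PRESETS["HL"], alloc)
        t = res.table
        stacked = t[["v_c_auto", "v_n", "v_p"]].to_numpy()
        assert np.allclose(t["mu_auto"], stacked.min(axis=1))
        names = np.array(["light", "N", "P"], dtype=object)
        assert (t["limiter"] == names[np.argmin(stacked, axis=1)]).all()

    def test_dark_depth_is_light_limited(self, alloc):
        env = EnvironmentProfile(depth=[0.0, 50.0], noon_par=[100.0, 0.0],
                                 din=[1e-3, 1e-3], po4=[1e-4, 1e-4])
        res = autotrophic_profile(env, PHOTOPHYS_PRESETS["HL"], alloc)
        assert res.table["mu_auto"].iloc[1] == 0.0
        assert res.table["limiter"].iloc[1] == "light"

    def test_limiter_switches_nutrient_to_light_at_single_crossover(
            self, synth_env, alloc):
        res = autotrophic_profile(synth_env, PHOTOPHYS_PRESETS["HL"], alloc)
        is_light = (res.table["limiter"] == "light").to_numpy()
        # nutrient-limited surface, light-limited depths, one switch
        assert not is_light[0]
        assert is_light[-1]
        assert np.count_nonzero(np.diff(is_light.astype(int)) != 0) == 1

    def test_iron_included_only_when_measured(self, alloc):
        env = EnvironmentProfile(depth=[0.0, 50.0], noon_par=[600.0, 60.0],
                                 din=[1e-3, 1e-3], po4=[1e-4, 1e-4],
                                 fe=[0.01, 0.5])
        nut = NutrientUptakeParams()
        res = autotrophic_profile(env, PHOTOPHYS_PRESETS["HL"], alloc, nut)
        # below-detection surface iron is lifted to the detection limit
        expected_surface = nut.k_fe_sa * nut.surface_area \
            * nut.fe_detection_limit / nut.q_fe
        assert res.table["v_fe"].iloc[0] == pytest.approx(expected_surface)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            EnvironmentProfile(depth=[], noon_par=[], din=[], po4=[])


class TestHeterotrophicInference:
    def test_subtraction_and_clamp(self):
        res = _make_result([0, 10, 20], [0.05, 0.4, 0.1], [0.2, 0.2, 0.2])
        res = infer_heterotrophic_rate(res)
        assert res.mu_het[0] == pytest.approx(0.15)
        assert res.mu_het[1] == 0.0
        assert res.mu_het[2] == pytest.approx(0.1)

    def test_interpolation_fills_gaps_but_never_extrapolates(self):
        res = _make_result([0, 10, 20, 30], [0.1] * 4,
                           [np.nan, 0.2, np.nan, 0.4])
        res = infer_heterotrophic_rate(res)
        obs = res.table["mu_obs"].to_numpy()
        assert np.isnan(obs[0])          # above the shallowest observation
        assert obs[2] == pytest.approx(0.3)  # linear between 10 and 30 m
        assert np.isnan(res.mu_het[0])

    def test_all_missing_observed_growth_rejected(self):
        res = _make_result([0, 10], [0.1, 0.1], [np.nan, np.nan])
        with pytest.raises(ValueError):
            infer_heterotrophic_rate(res)

    def test_envelope_brackets_every_scenario(self, synth_env, alloc):
        results = []
        for name in ("HL", "LL"):
            base = PHOTOPHYS_PRESETS[name]
            for p in (base, base.with_beta(0.0)):
                results.append(autotrophic_profile(synth_env, p, alloc))
        env = scenario_envelope(results)
        for r in results:
            assert np.all(r.mu_auto >= env["mu_auto_min"].to_numpy() - 1e-12)
            assert np.all(r.mu_auto <= env["mu_auto_max"].to_numpy() + 1e-12)


class TestProduction:
    def test_uniform_profile_hand_integral(self):
        # mu = 0.5/day, n = 1e8 cells/m^3, Q = 50 fg C over 100 m
        depth = np.linspace(0, 100, 11)
        res = _make_result(depth, np.full(11, 0.5), np.full(11, 0.5))
        res = infer_heterotrophic_rate(res)
        prod = integrate_production(res, cell_density=np.full(11, 1e8),
                                    carbon_quota=50e-15)
        assert prod.autotrophic_g_c_m2_day == pytest.approx(2.5e-4, rel=1e-9)
        assert prod.heterotrophic_g_c_m2_day == 0.0
        assert prod.heterotrophic_fraction_pct == 0.0

    def test_quota_scale_invariance_of_fractions(self):
        depth = np.linspace(0, 100, 21)
        mu_auto = np.linspace(0.4, 0.0, 21)
        res = infer_heterotrophic_rate(
            _make_result(depth, mu_auto, np.full(21, 0.2)))
        dens = np.full(21, 1e10)
        one = integrate_production(res, dens, carbon_quota=50e-15)
        two = integrate_production(res, dens, carbon_quota=100e-15)
        assert two.autotrophic_g_c_m2_day \
            == pytest.approx(2 * one.autotrophic_g_c_m2_day)
        assert two.heterotrophic_fraction_pct \
            == pytest.approx(one.heterotrophic_fraction_pct)

    def test_below_onset_fraction_exceeds_overall_on_synthetic_fixture(
            self, synth_env, alloc):
        res = autotrophic_profile(synth_env, PHOTOPHYS_PRESETS["HL"], alloc)
        res = infer_heterotrophic_rate(res)
        prod = integrate_production(res)
        assert prod.heterotrophic_fraction_pct > 0.0
        assert prod.below_onset_heterotrophic_fraction_pct \
            > prod.heterotrophic_fraction_pct


class TestOnsetDepth:
    def test_no_heterotrophy_means_no_onset(self):
        res = infer_heterotrophic_rate(
            _make_result([0, 50, 100], [0.5, 0.5, 0.5], [0.2, 0.2, 0.2]))
        onset, par = mixotrophy_onset_depth(res)
        assert onset is None and par is None

    def test_linear_crossing_arithmetic(self):
        # mu_auto falls linearly 0.4 -> 0 over 0-100 m; mu_obs = 0.2.
        # mu_het = max(0, 0.2 - mu_auto) first exceeds mu_auto where
        # 0.2 - mu_auto > mu_auto, i.e. mu_auto < 0.1, at exactly 75 m;
        # mu_het itself first turns positive at 50 m.
        depth = np.linspace(0, 100, 101)
        mu_auto = np.linspace(0.4, 0.0, 101)
        res = infer_heterotrophic_rate(
            _make_result(depth, mu_auto, np.full(101, 0.2)))
        onset, _ = mixotrophy_onset_depth(res)
        assert onset == pytest.approx(75.0, abs=1e-9)
        assert mixotrophy_first_positive(res) == pytest.approx(50.0, abs=1e-9)

    def test_onset_par_matches_attenuated_light(self):
        depth = np.linspace(0, 100, 101)
        mu_auto = np.linspace(0.4, 0.0, 101)
        res = infer_heterotrophic_rate(
            _make_result(depth, mu_auto, np.full(101, 0.2)))
        onset, par = mixotrophy_onset_depth(res)
        assert par == pytest.approx(600.0 * np.exp(-0.045 * onset), rel=1e-3)

    def test_first_positive_shallower_than_dominance_onset(self):
        depth = np.linspace(0, 100, 101)
        mu_auto = np.linspace(0.4, 0.0, 101)
        res = infer_heterotrophic_rate(
            _make_result(depth, mu_auto, np.full(101, 0.2)))
        first = mixotrophy_first_positive(res)
        onset, _ = mixotrophy_onset_depth(res)
        assert first < onset
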
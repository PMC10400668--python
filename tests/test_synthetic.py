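"""Generator determinism, design structure, climate and truth relations."""

import numpy as np
import pandas as pd
import pytest

from thermacclim.aci import curves_from_table, fit_aci_bilinear
from thermacclim.fvcb import PeakedArrheniusParams, peaked_arrhenius
from thermacclim.synthetic import (CA_SEQUENCE, LinearRelation,
                                   SpeciesAcclimation, SyntheticConfig,
                                   TAMARACK, _EmergentCalibrator,
                                   generate_aci_curves, generate_climate,
                                   generate_design, generate_experiment,
                                   generate_tree_truth)
from thermacclim.thermal import TemperatureSeries, fit_quadratic_topt
from thermacclim.aci import extract_growth_a


class TestDesign:
    def test_default_design_has_ten_plots(self):
        roster = generate_design(SyntheticConfig(), 0)
        assert roster.plot_id.nunique() == 10
        combos = roster.groupby(["warming_offset_c", "co2_treatment"]).ngroups
        assert combos == 10

    def test_tree_month_unit_count(self):
        cfg = SyntheticConfig(trees_per_plot=3, species=("tamarack",))
        roster = generate_design(cfg, 0)
        # 10 plots x 3 trees x 2 months
        assert len(roster) == 60

    def test_same_seed_identical_roster(self):
        r1 = generate_design(SyntheticConfig(), 5)
        r2 = generate_design(SyntheticConfig(), 5)
        pd.testing.assert_frame_equal(r1, r2)


class TestClimate:
    def test_daytime_mean_differences_equal_warming_offsets(self):
        cfg = SyntheticConfig(climate_sigma=0.0)
        clim = generate_climate(cfg, 0)
        day = clim[(clim.timestamp.dt.hour >= 9)
                   & (clim.timestamp.dt.hour < 15)]
        means = day.groupby("plot_id").air_temp_c.mean()
        assert means["P09"] - means["P01"] == pytest.approx(9.0, abs=1e-12)
        assert means["P03"] - means["P01"] == pytest.approx(2.25, abs=1e-12)

    def test_offsets_hold_with_weather_noise_shared_across_plots(self):
        clim = generate_climate(SyntheticConfig(), 3)
        day = clim[(clim.timestamp.dt.hour >= 9)
                   & (clim.timestamp.dt.hour < 15)]
        means = day.groupby("plot_id").air_temp_c.mean()
        assert means["P09"] - means["P01"] == pytest.approx(9.0, abs=0.3)

    def test_noiseless_daytime_mean_matches_cosine_integral(self):
        cfg = SyntheticConfig(climate_sigma=0.0)
        clim = generate_climate(cfg, 0)
        day = clim[(clim.plot_id == "P01") & (clim.timestamp.dt.hour >= 9)
                   & (clim.timestamp.dt.hour < 15)]
        # analytic mean of base + amp*cos(2pi(h-15)/24) over [9, 15),
        # with the half-hourly left-endpoint sampling correction amp*dt/12
        analytic = 19.0 + 6.0 * 2.0 / np.pi - 6.0 * 0.5 / 12.0
        assert day.air_temp_c.mean() == pytest.approx(analytic, abs=0.02)

    def test_same_seed_identical_series(self):
        c1 = generate_climate(SyntheticConfig(), 9)
        c2 = generate_climate(SyntheticConfig(), 9)
        pd.testing.assert_frame_equal(c1, c2)


class TestTruth:
    def test_linear_arithmetic_with_all_noise_off(self, noiseless_config,
                                                  noiseless_experiment):
        truth = noiseless_experiment["truth"]
        tam = truth[(truth.species == "tamarack") & (truth.month == "June")]
        plus9_a = tam[(tam.warming_offset_c == 9.0)
                      & (tam.co2_treatment == "aCO2")]
        assert np.allclose(plus9_a.topt_a, 23.2 + 0.26 * 9.0)
        ctrl_a = tam[(tam.warming_offset_c == 0.0)
                     & (tam.co2_treatment == "aCO2")]
        assert np.allclose(ctrl_a.topt_a, 23.2)

    def test_co2_offset_exact_at_every_warming_level(self,
                                                     noiseless_experiment):
        truth = noiseless_experiment["truth"]
        tam = truth[(truth.species == "tamarack") & (truth.month == "June")]
        for w in (0.0, 2.25, 4.5, 6.75, 9.0):
            a = tam[(tam.warming_offset_c == w)
                    & (tam.co2_treatment == "aCO2")].topt_a.iloc[0]
            e = tam[(tam.warming_offset_c == w)
                    & (tam.co2_treatment == "eCO2")].topt_a.iloc[0]
            assert e - a == pytest.approx(3.0, abs=1e-9)

    def test_large_sample_truth_slope_regresses_to_configured(self):
        # many tree truths; the empirical warming slope of the generated
        # ToptA truths must match the configured 0.26 closely
        cfg = SyntheticConfig(species=("tamarack",), trees_per_plot=4)
        rows = []
        for seed in range(40):
            roster = generate_design(cfg, seed)
            truth = generate_tree_truth(cfg, roster, seed)
            rows.append(truth[truth.co2_treatment == "aCO2"])
        truth = pd.concat(rows)
        slope = np.polyfit(truth.warming_offset_c, truth.topt_a, 1)[0]
        assert slope == pytest.approx(0.26, abs=0.02)

    def test_calibration_makes_emergent_quadratic_match_truth(
            self, noiseless_experiment):
        """The quadratic fit of noiseless growth-Ci A(T) equals the
        recorded (topt_a, aopt, b) truth for every tree."""
        truth = noiseless_experiment["truth"]
        curves = curves_from_table(noiseless_experiment["aci_curves"])
        growth = {"aCO2": 400.0, "eCO2": 800.0}
        by_tree = {}
        for c in curves:
            by_tree.setdefault(
                (c.plot_id, c.species, c.tree_id, c.month), []).append(c)
        for key, cs in list(by_tree.items())[:20]:
            cs.sort(key=lambda c: c.tleaf)
            fit = fit_quadratic_topt(TemperatureSeries(
                tuple(c.tleaf for c in cs),
                tuple(extract_growth_a(c, growth[c.co2_treatment])
                      for c in cs)))
            row = truth[(truth.plot_id == key[0]) & (truth.species == key[1])
                        & (truth.tree_id == key[2])
                        & (truth.month == key[3])].iloc[0]
            assert fit.topt_a == pytest.approx(row.topt_a, abs=5e-7)
            assert fit.aopt == pytest.approx(row.aopt, abs=1e-7)
            assert fit.b == pytest.approx(row.b, rel=1e-4)

    def test_inline_peaked_formula_agrees_with_public_function(self):
        tk = np.linspace(280.0, 320.0, 9)
        ours = _EmergentCalibrator._peaked(75.0, 31.0, 48.0, tk)
        ref = peaked_arrhenius(
            PeakedArrheniusParams(75.0, 31.0 + 273.15, 48.0, 200.0), tk)
        assert np.allclose(ours, ref, rtol=1e-12)


class TestCurves:
    def test_printed_ca_sequence_and_eleven_steps(self, noisy_experiment):
        curves = noisy_experiment["aci_curves"]
        one = curves[(curves.plot_id == "P01")
                     & (curves.species == "tamarack")
                     & (curves.tree_id == "tamT1")
                     & (curves.month == "June")
                     & (curves.tleaf_c == 25.0)]
        assert len(one) == 11
        assert tuple(one.sort_values("step_index").ca_ppm) == CA_SEQUENCE

    def test_constant_ci_ca_ratio(self, noisy_experiment):
        curves = noisy_experiment["aci_curves"]
        assert np.allclose(curves.ci_ppm, 0.7 * curves.ca_ppm)

    def test_noiseless_curves_refit_recovers_vcmax_to_point1_percent(
            self, noiseless_experiment, constants):
        truth = noiseless_experiment["truth"]
        curves = curves_from_table(noiseless_experiment["aci_curves"])
        checked = 0
        for c in curves:
            if c.tleaf != 25.0 or c.species != "tamarack":
                continue
            row = truth[(truth.plot_id == c.plot_id)
                        & (truth.species == c.species)
                        & (truth.tree_id == c.tree_id)
                        & (truth.month == c.month)].iloc[0]
            expected = peaked_arrhenius(
                PeakedArrheniusParams(row.kopt_v, row.topt_v + 273.15,
                                      row.ea_v), 298.15)
            fit = fit_aci_bilinear(c, constants)
            assert abs(fit.vcmax - expected) / expected < 1e-3
            checked += 1
            if checked >= 10:
                break
        assert checked == 10

    def test_seed_determinism_and_divergence(self):
        cfg = SyntheticConfig(species=("tamarack",), trees_per_plot=1)
        e1 = generate_experiment(cfg, 7)
        e2 = generate_experiment(cfg, 7)
        e3 = generate_experiment(cfg, 8)
        pd.testing.assert_frame_equal(e1["aci_curves"], e2["aci_curves"])
        assert not e1["aci_curves"].a_umol_m2_s.equals(
            e3["aci_curves"].a_umol_m2_s)


class TestConfigValidation:
    def test_wrong_ca_step_count_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(ca_steps=(400.0, 300.0, 200.0))

    def test_nonphysical_acclimation_rejected(self):
        bad = SpeciesAcclimation(
            topt_a=LinearRelation(4.0),  # below the physical floor
            topt_v=LinearRelation(33.0), topt_j=LinearRelation(31.8),
            aopt=LinearRelation(7.9), b=LinearRelation(0.02))
        cfg = SyntheticConfig(species=("tamarack",),
                              acclimation={"tamarack": bad},
                              sigma_topt_plot=0.0, sigma_topt_tree=0.0)
        roster = generate_design(cfg, 0)
        with pytest.raises(ValueError):
            generate_tree_truth(cfg, roster, 0)
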
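"""Plot-mean aggregation, mixed-model selection, one-sided tests, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermacclim.inference import (aggregate_plot_means, aicc_from_aic,
                                   anova_delta_tg, fit_candidates,
                                   one_sided_p, select_model)

WARMING = [0.0, 2.25, 4.5, 6.75, 9.0]


def plot_mean_table(value_fn, noise=0.0, seed=0, months=("June", "August")):
    """Long-format plot-means table over the 10-plot design."""
    rng = np.random.default_rng(seed)
    rows = []
    p = 0
    for w in WARMING:
        for co2 in ("aCO2", "eCO2"):
            p += 1
            for month in months:
                rows.append({
                    "plot_id": f"P{p:02d}", "warming_offset_c": w,
                    "co2_treatment": co2, "species": "tamarack",
                    "month": month, "response_name": "topt_a",
                    "value": value_fn(w, co2 == "eCO2", month)
                    + rng.normal(0, noise),
                    "n_trees": 3})
    return pd.DataFrame(rows)


class TestAggregation:
    def test_simple_means_and_counts(self):
        trees = pd.DataFrame({
            "plot_id": ["P01", "P01", "P02"],
            "warming_offset_c": [0.0, 0.0, 2.25],
            "co2_treatment": ["aCO2", "aCO2", "aCO2"],
            "species": ["tamarack"] * 3,
            "month": ["June"] * 3,
            "topt_a": [22.0, 24.0, 25.0],
        })
        means = aggregate_plot_means(trees, ("topt_a",))
        p1 = means[means.plot_id == "P01"].iloc[0]
        p2 = means[means.plot_id == "P02"].iloc[0]
        assert p1.value == 23.0 and p1.n_trees == 2
        assert p2.value == 25.0 and p2.n_trees == 1

    def test_matches_brute_force_groupby_on_shuffled_table(self):
        rng = np.random.default_rng(1)
        trees = pd.DataFrame({
            "plot_id": rng.choice(["P01", "P02", "P03"], 60),
            "warming_offset_c": 0.0, "co2_treatment": "aCO2",
            "species": "tamarack",
            "month": rng.choice(["June", "August"], 60),
            "topt_a": rng.normal(24, 2, 60),
        })
        means = aggregate_plot_means(trees, ("topt_a",))
        for r in means.itertuples():
            mask = (trees.plot_id == r.plot_id) & (trees.month == r.month)
            assert r.value == pytest.approx(trees.loc[mask, "topt_a"].mean())
            assert r.n_trees == int(mask.sum())


class TestCandidates:
    def test_aicc_arithmetic(self):
        assert aicc_from_aic(100.0, 4, 10) == pytest.approx(108.0)

    def test_zero_noise_slope_recovered_exactly(self):
        data = plot_mean_table(lambda w, e, m: 0.3 * w + 23.0)
        cands = fit_candidates(data, "topt_a")
        ols_main = next(c for c in cands if c.random_structure == "none"
                        and c.fixed_structure == "main_effects"
                        and c.estimation == "ML")
        assert ols_main.coefficients["warming"][0] == pytest.approx(
            0.3, abs=1e-10)
        assert ols_main.coefficients["co2e"][0] == pytest.approx(
            0.0, abs=1e-10)

    def test_ml_loglik_matches_closed_form_gaussian(self):
        data = plot_mean_table(lambda w, e, m: 0.3 * w + 23.0 + 2 * e,
                               noise=0.8, seed=2)
        cands = fit_candidates(data, "topt_a")
        c = next(c for c in cands if c.random_structure == "none"
                 and c.fixed_structure == "main_effects"
                 and c.estimation == "ML")
        df = data.copy()
        X = np.column_stack([np.ones(len(df)), df.warming_offset_c,
                             (df.co2_treatment == "eCO2").astype(float)])
        y = df.value.to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        n = len(y)
        sigma2 = resid @ resid / n
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
        assert c.loglik == pytest.approx(ll, rel=1e-9)


class TestSelection:
    def test_month_random_intercept_selected_under_strong_month_shift(self):
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            data = plot_mean_table(
                lambda w, e, m: 0.3 * w + 23.0 + (5.0 if m == "June" else 0),
                noise=0.5, seed=seed)
            out = select_model(fit_candidates(data, "topt_a"), "topt_a")
            hits += out.selected.random_structure == "month_intercept"
        assert hits >= 0.95 * n_seeds

    def test_interaction_selected_when_slopes_differ(self):
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            data = plot_mean_table(
                lambda w, e, m: (0.3 + 0.5 * e) * w + 23.0,
                noise=0.3, seed=seed)
            out = select_model(fit_candidates(data, "topt_a"), "topt_a")
            hits += out.selected.fixed_structure == "interaction"
        assert hits >= 0.90 * n_seeds

    def test_ties_break_toward_simpler_structures(self):
        # zero-noise, no month or CO2 effect: AICs equal to numerical
        # precision never arise, but the simpler structure must win when
        # the richer one does not improve the likelihood materially
        data = plot_mean_table(lambda w, e, m: 0.3 * w + 23.0, noise=0.2,
                               seed=7)
        out = select_model(fit_candidates(data, "topt_a"), "topt_a")
        assert out.selected.random_structure == "none"
        assert out.selected.fixed_structure == "main_effects"

    def test_reml_aic_of_no_random_model_consistent_with_mixed(self):
        # with a tiny true month variance both REML AICs must be close,
        # and the mixed one must not win by a large margin
        data = plot_mean_table(lambda w, e, m: 0.3 * w + 23.0,
                               noise=0.5, seed=3)
        cands = fit_candidates(data, "topt_a")
        rml = {c.random_structure: c.aic for c in cands
               if c.estimation == "REML" and c.fixed_structure == "interaction"
               and c.estimable}
        if "month_intercept" in rml:
            assert rml["month_intercept"] >= rml["none"] - 0.5

    def test_selection_invariant_to_row_order_and_location_shift(self):
        data = plot_mean_table(lambda w, e, m: 0.3 * w + 23.0 + 2 * e,
                               noise=0.4, seed=5)
        out1 = select_model(fit_candidates(data, "topt_a"), "topt_a")
        shuffled = data.sample(frac=1.0, random_state=0).reset_index(
            drop=True)
        shuffled["value"] = shuffled["value"] + 100.0
        out2 = select_model(fit_candidates(shuffled, "topt_a"), "topt_a")
        assert out1.selected.random_structure == out2.selected.random_structure
        assert out1.selected.fixed_structure == out2.selected.fixed_structure
        assert out2.warming_slope["aCO2"] == pytest.approx(
            out1.warming_slope["aCO2"], abs=1e-6)


class TestOneSidedP:
    def test_zero_estimate_gives_half(self):
        assert one_sided_p(0.0, 1.0, 10) == pytest.approx(0.5)

    def test_large_estimate_tends_to_zero(self):
        assert one_sided_p(100.0, 1.0, 10) < 1e-10

    def test_t_table_oracle(self):
        # published one-sided critical values for df=10:
        # t(0.025)=2.228, t(0.01)=2.764, so p(t=2.5) lies between
        p = one_sided_p(2.5, 1.0, 10)
        assert 0.01 < p < 0.025
        assert p == pytest.approx(float(stats.t.sf(2.5, 10)), rel=1e-12)

    def test_less_direction(self):
        assert one_sided_p(-2.0, 1.0, 10, "less") == pytest.approx(
            float(stats.t.cdf(-2.0, 10)), rel=1e-12)


def delta_table(value_fn, noise=0.0, seed=0):
    df = plot_mean_table(value_fn, noise=noise, seed=seed)
    return df.assign(response_name="delta_mean_tg")


class TestDeltaTgAnova:
    def test_equal_means_give_zero_factor_ss(self):
        # constant response: every factor sum of squares is numerically
        # zero (the F ratio itself is 0/0 and not meaningful)
        tab = anova_delta_tg(delta_table(lambda w, e, m: 2.5))
        assert tab.loc["C(warming_offset_c)", "sum_sq"] == pytest.approx(
            0.0, abs=1e-12)
        assert tab.loc["C(co2_treatment)", "sum_sq"] == pytest.approx(
            0.0, abs=1e-12)

    def test_single_factor_shift_detected_against_hand_anova(self):
        # CO2 shifts by 2, no warming effect: hand-computed SS on the
        # balanced 5x2x2 table
        tab = anova_delta_tg(delta_table(
            lambda w, e, m: 3.0 + 2.0 * e, noise=0.1, seed=1))
        data = delta_table(lambda w, e, m: 3.0 + 2.0 * e, noise=0.1, seed=1)
        g = data.groupby("co2_treatment").value
        n_per = len(data) / 2
        ss_co2_hand = float(n_per * ((g.mean() - data.value.mean()) ** 2).sum())
        assert tab.loc["C(co2_treatment)", "sum_sq"] == pytest.approx(
            ss_co2_hand, rel=1e-6)
        assert tab.loc["C(co2_treatment)", "PR(>F)"] < 1e-6
        assert tab.loc["C(warming_offset_c)", "PR(>F)"] > 0.1

    def test_balanced_ss_decomposition(self):
        data = delta_table(lambda w, e, m: 2.0 + 0.2 * w + e, noise=0.5,
                           seed=4)
        tab = anova_delta_tg(data)
        total = float(((data.value - data.value.mean()) ** 2).sum())
        parts = float(tab.sum_sq.sum())
        assert parts == pytest.approx(total, rel=1e-9)
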
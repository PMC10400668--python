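"""Parameter-recovery protocols on synthetic experiments.

The headline results this package targets are regression estimates on
field data (warming slopes of thermal optima, CO2 intercept shifts,
curvature ratios, slopes between optima). Since those cannot be
recomputed from the publication alone, validation works by *recovery*:
the quantities are embedded as generator truth, the pipeline is run
end-to-end on many seeded synthetic replicates, and the mean recovered
estimate is compared with the embedded value.

Each protocol here runs one replicate and returns the recovered
estimates; :func:`run_replicates` averages any protocol over seeds.
All randomness flows from a single ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from . import aci, inference, thermal
from .fvcb import PeakedArrheniusParams, peaked_arrhenius
from .synthetic import (BLACK_SPRUCE, TAMARACK, SyntheticConfig,
                        generate_aci_curves, generate_design,
                        generate_tree_truth)

__all__ = [
    "run_replicates",
    "species_recovery",
    "paired_optima_slope",
    "topt_j_slope_spruce",
]

GROWTH_CA = {"aCO2": 400.0, "eCO2": 800.0}


def _mixed_slope(df: pd.DataFrame, formula: str,
                 groups: str = "month") -> dict[str, float]:
    """Fixed-effect estimates of a month-random-intercept model.

    When the profiled month variance collapses to the boundary (zero)
    the mixed fit can fail numerically; the model then *is* ordinary
    least squares, which is used as the fallback.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = smf.mixedlm(formula, df, groups=df[groups]).fit(
                reml=False, method=["lbfgs", "powell"])
        params = res.fe_params
    except (np.linalg.LinAlgError, ValueError):
        params = smf.ols(formula, df).fit().params
    return {k: float(v) for k, v in params.items()}


def _quadratic_fits(curves: pd.DataFrame) -> pd.DataFrame:
    """Growth-CO2 A extraction and quadratic fit per tree × month."""
    growth = aci.extract_growth_a_table(curves, GROWTH_CA)
    rows = []
    for key, grp in growth.groupby(
            ["plot_id", "species", "co2_treatment", "warming_offset_c",
             "tree_id", "month"], sort=False):
        fit = thermal.fit_quadratic_topt(thermal.TemperatureSeries(
            tuple(grp.tleaf_c), tuple(grp.a_growth), "Anet"))
        if not fit.converged:
            continue
        rows.append(dict(zip(
            ["plot_id", "species", "co2_treatment", "warming_offset_c",
             "tree_id", "month"], key),
            topt_a=fit.topt_a, aopt=fit.aopt, b=fit.b))
    return pd.DataFrame(rows)


def _experiment_curves(species: str, seed: int) -> pd.DataFrame:
    """One default-condition synthetic experiment for one species."""
    config = SyntheticConfig(species=(species,))
    ss = np.random.SeedSequence(seed)
    s_truth, s_curves = (int(s) for s in ss.generate_state(2))
    roster = generate_design(config, s_truth)
    truth = generate_tree_truth(config, roster, s_truth)
    return generate_aci_curves(truth, config, s_curves)


def species_recovery(species: str, seed: int) -> dict[str, float]:
    """End-to-end recovery of all quadratic-response quantities.

    Generates one full experiment for ``species``, extracts growth-CO2
    A from every curve, fits the quadratic temperature response per
    tree × month, and derives:

    * the ToptA warming slope and CO2 intercept shift from the
      main-effects mixed model (month random intercept) on plot means;
    * the percent elevation of the fitted curvature b under elevated
      CO2 (100·(mean b eCO2 / mean b aCO2 − 1));
    * the Aopt warming slope within the elevated-CO2 plots (the
      per-CO2-level regression line).
    """
    fits = _quadratic_fits(_experiment_curves(species, seed))
    means = inference.aggregate_plot_means(fits, ("topt_a", "aopt", "b"))
    out: dict[str, float] = {}

    df = means[means.response_name == "topt_a"].copy()
    df["co2e"] = (df.co2_treatment == "eCO2").astype(float)
    df["warming"] = df.warming_offset_c
    coefs = _mixed_slope(df, "value ~ warming + co2e")
    out["topt_a_warming_slope"] = coefs["warming"]
    out["topt_a_co2_shift"] = coefs["co2e"]
    out["topt_a_intercept"] = coefs["Intercept"]

    g = fits.groupby("co2_treatment").b.mean()
    out["b_elevation_pct"] = 100.0 * (g["eCO2"] / g["aCO2"] - 1.0)

    df = means[(means.response_name == "aopt")
               & (means.co2_treatment == "eCO2")].copy()
    df["warming"] = df.warming_offset_c
    out["aopt_slope_eco2"] = _mixed_slope(df, "value ~ warming")["warming"]
    return out


def paired_optima_slope(which: str, seed: int, n_plots: int = 20,
                        sigma_y: float = 0.7) -> dict[str, float]:
    """Recovered slope of the ToptA-vs-biochemical-optimum relation.

    Generates plot-level pairs from the configured tamarack ambient
    relation: the biochemical optimum (``which`` = "topt_v" or
    "topt_j") follows its warming relation over ``n_plots`` warming
    levels spanning 0–9 °C with plot noise, ToptA follows the linear
    relation between optima plus Gaussian noise ``sigma_y``, for two
    months; the slope is estimated with a month random intercept.
    """
    relations = {"topt_v": (0.57, 4.4), "topt_j": (0.75, -0.62)}
    slope, intercept = relations[which]
    rng = np.random.default_rng(seed)
    warm = np.linspace(0.0, 9.0, n_plots)
    base = TAMARACK.topt_v if which == "topt_v" else TAMARACK.topt_j
    rows = []
    for month, dm in (("June", 0.0), ("August", 0.5)):
        x = np.array([base(w, False) for w in warm]) + dm \
            + rng.normal(0.0, 0.5, n_plots)
        y = slope * x + intercept + rng.normal(0.0, sigma_y, n_plots)
        rows.append(pd.DataFrame({"x": x, "value": y, "month": month}))
    df = pd.concat(rows, ignore_index=True)
    coefs = _mixed_slope(df, "value ~ x")
    return {"slope": coefs["x"]}


def topt_j_slope_spruce(seed: int, trees_per_plot: int = 3) -> dict[str, float]:
    """Warming slope of the fitted ToptJ in spruce for one replicate.

    Per tree: true ToptJ follows the spruce warming relation plus plot
    (σ = 0.5 °C) and tree (σ = 0.3 °C) noise; Jmax at the five
    measurement temperatures comes from the peaked Arrhenius function
    (Hd fixed at 200 kJ mol^-1) with 5 % multiplicative value noise;
    the function is refitted per tree and plot-mean ToptJ regressed on
    the warming offset.
    """
    rng = np.random.default_rng(seed)
    sp = BLACK_SPRUCE
    temps = (15.0, 25.0, 32.5, 40.0, 45.0)
    tk = np.asarray(temps) + 273.15
    rows = []
    for i, warm in enumerate(np.repeat([0.0, 2.25, 4.5, 6.75, 9.0], 2)):
        plot_shift = rng.normal(0.0, 0.5)
        for t in range(trees_per_plot):
            topt_true = sp.topt_j(warm, False) + plot_shift \
                + rng.normal(0.0, 0.3)
            kopt = sp.jmax_vcmax_ratio * sp.kopt_v_base \
                * rng.lognormal(0.0, 0.1)
            vals = peaked_arrhenius(
                PeakedArrheniusParams(kopt, topt_true + 273.15,
                                      sp.ea_j_base), tk)
            vals = vals * rng.lognormal(0.0, 0.05, len(vals))
            fit = thermal.fit_peaked_arrhenius(
                thermal.TemperatureSeries(temps, tuple(vals), "Jmax"))
            rows.append({"plot": i, "warming": warm, "topt_j": fit.topt})
    df = pd.DataFrame(rows)
    means = df.groupby(["plot", "warming"], as_index=False).topt_j.mean()
    fit = smf.ols("topt_j ~ warming", means).fit()
    return {"warming_slope": float(fit.params["warming"])}


def run_replicates(protocol: Callable[[int], dict[str, float]],
                   n_replicates: int, base_seed: int) -> pd.DataFrame:
    """Run a recovery protocol across seeded replicates.

    Seeds are spawned from ``base_seed`` via a SeedSequence so each
    replicate is independent and the whole set is reproducible.
    """
    children = np.random.SeedSequence(base_seed).spawn(n_replicates)
    rows = [protocol(int(child.generate_state(1)[0] % (2 ** 31)))
            for child in children]
    return pd.DataFrame(rows)
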
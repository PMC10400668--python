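"""Plot-level regression protocol for the warming × CO2 experiment.

The experimental design is regression-based: five warming offsets
(0 … +9 °C) crossed with two atmospheric CO2 levels, analysed on plot
means (1–4 trees per plot) with warming as a continuous covariate, CO2
as a two-level factor, and the measurement month as a candidate random
intercept. Model selection follows the two-step protocol standard in
ecological mixed modelling: the random structure is chosen first by
REML AIC (comparing against the no-random generalized least-squares
model under the richest fixed structure), then the fixed structure
(main effects vs interaction) by ML AIC, with AICc reported alongside
because the design is small. Directional treatment hypotheses use
one-sided t probabilities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "CandidateModel",
    "SelectionOutcome",
    "aggregate_plot_means",
    "fit_candidates",
    "select_model",
    "one_sided_p",
    "anova_delta_tg",
    "aicc_from_aic",
]

log = logging.getLogger(__name__)

RESPONSES = ("topt_a", "aopt", "b", "topt_v", "topt_j", "ea_v", "ea_j",
             "a_g", "delta_mean_tg", "topt_a70")

# responses with a directional (increase-under-treatment) hypothesis
ONE_SIDED_RESPONSES = frozenset({"topt_a", "aopt", "a_g"})


@dataclass
class CandidateModel:
    """One fitted candidate in the two-step selection."""

    random_structure: str   # "none" | "month_intercept"
    fixed_structure: str    # "main_effects" | "interaction"
    estimation: str         # "REML" | "ML"
    coefficients: dict[str, tuple[float, float]]  # name -> (estimate, se)
    loglik: float
    aic: float
    aicc: float
    n: int
    k: int
    estimable: bool = True
    message: str = ""


@dataclass
class SelectionOutcome:
    """Selected model structure and treatment-effect estimates."""

    response_name: str
    selected: CandidateModel
    all_candidates: list[CandidateModel]
    warming_slope: dict[str, float]        # per CO2 level
    warming_slope_se: dict[str, float]
    co2_intercept_shift: float
    intercept: float
    one_sided_p: dict[str, float]          # per slope (CO2 level)
    residual_df: int


def aicc_from_aic(aic: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: AICc = AIC + 2k(k+1)/(n − k − 1)."""
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def aggregate_plot_means(tree_rows: pd.DataFrame,
                         responses: tuple[str, ...] = RESPONSES,
                         ) -> pd.DataFrame:
    """Arithmetic plot means per plot × month × response (long format).

    ``tree_rows`` has one row per tree × month with the response
    columns present; trees with failed fits must already be excluded.
    Empty plots simply do not appear. ``n_trees`` records how many
    trees entered each mean.
    """
    present = [r for r in responses if r in tree_rows.columns]
    key = ["plot_id", "warming_offset_c", "co2_treatment", "species", "month"]
    out = []
    for resp in present:
        grp = (tree_rows.dropna(subset=[resp])
               .groupby(key, sort=False, dropna=False)[resp]
               .agg(["mean", "count"]).reset_index())
        grp = grp.rename(columns={"mean": "value", "count": "n_trees"})
        grp["response_name"] = resp
        out.append(grp)
    if not out:
        raise ValueError("no known response columns in tree table")
    return pd.concat(out, ignore_index=True)


def _prepare(data: pd.DataFrame) -> pd.DataFrame:
    df = data.copy()
    df["co2e"] = (df["co2_treatment"] == "eCO2").astype(float)
    df["warming"] = df["warming_offset_c"].astype(float)
    return df.dropna(subset=["value"])


_FIXED_FORMULAS = {
    "main_effects": "value ~ warming + co2e",
    "interaction": "value ~ warming * co2e",
}


def _fit_one(df: pd.DataFrame, fixed: str, random: str,
             reml: bool) -> CandidateModel:
    """Fit a single candidate; non-estimable fits are flagged, not raised."""
    formula = _FIXED_FORMULAS[fixed]
    n = len(df)
    est = "REML" if reml else "ML"
    try:
        if random == "month_intercept":
            if df["month"].nunique() < 2:
                raise ValueError("random intercept needs >= 2 months")
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    res = smf.mixedlm(formula, df, groups=df["month"]).fit(
                        reml=reml, method=["lbfgs", "powell"])
                p_fixed = len(res.fe_params)
                loglik = float(res.llf)
                coefs = {name: (float(res.fe_params[name]),
                                float(res.bse_fe[name]))
                         for name in res.fe_params.index}
            except np.linalg.LinAlgError:
                # month variance profiled to the boundary (zero): the
                # model degenerates to OLS with one extra (boundary)
                # variance parameter still counted in k
                ols = smf.ols(formula, df).fit()
                p_fixed = len(ols.params)
                loglik = _reml_loglik_ols(ols) if reml else float(ols.llf)
                coefs = {name: (float(ols.params[name]), float(ols.bse[name]))
                         for name in ols.params.index}
            k = p_fixed + 2  # + random-intercept variance + residual variance
        else:
            ols = smf.ols(formula, df).fit()
            p_fixed = len(ols.params)
            k = p_fixed + 1  # + residual variance
            loglik = _reml_loglik_ols(ols) if reml else float(ols.llf)
            coefs = {name: (float(ols.params[name]), float(ols.bse[name]))
                     for name in ols.params.index}
    except Exception as err:  # noqa: BLE001 - candidate flagged, not fatal
        log.warning("candidate (%s, %s, %s) non-estimable: %s",
                    random, fixed, est, err)
        return CandidateModel(random, fixed, est, {}, np.nan, np.inf, np.inf,
                              n, 0, estimable=False, message=str(err))
    aic = -2.0 * loglik + 2.0 * k
    return CandidateModel(random, fixed, est, coefs, loglik, aic,
                          aicc_from_aic(aic, k, n), n, k)


def _reml_loglik_ols(ols_result) -> float:
    """Restricted log-likelihood of an OLS fit.

    l_R = −½(n−p)[log 2π + log σ̂² + 1] − ½ log|X'X|, σ̂² = RSS/(n−p) —
    the same convention as the mixed-model restricted likelihood with
    the random variance at zero, so REML AICs are comparable across the
    two random structures.
    """
    X = np.asarray(ols_result.model.exog)
    n, p = X.shape
    rss = float(ols_result.ssr)
    sigma2 = rss / (n - p)
    _, logdet = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * (np.log(2 * np.pi) + np.log(sigma2) + 1.0)
                   + logdet)


def fit_candidates(data: pd.DataFrame, response_name: str,
                   ) -> list[CandidateModel]:
    """Fit the 2 random × 2 fixed candidate grid under REML and ML.

    ``data`` is the long plot-means table filtered (or filterable) to
    one response; needs >= 8 records. REML fits serve the
    random-structure comparison, ML fits the fixed-structure one.
    """
    df = data[data["response_name"] == response_name] \
        if "response_name" in data else data
    df = _prepare(df)
    if len(df) < 8:
        raise ValueError(
            f"{response_name}: need >= 8 plot-mean records, got {len(df)}")
    out = []
    for random in ("none", "month_intercept"):
        for fixed in ("main_effects", "interaction"):
            for reml in (True, False):
                out.append(_fit_one(df, fixed, random, reml))
    return out


def _pick(candidates: list[CandidateModel], order: list[str],
          attr: str) -> str | None:
    """Lowest-AIC structure; ties (within 1e-9) go to the earlier (simpler)
    entry of ``order``."""
    best, best_aic = None, np.inf
    for structure in order:
        for c in candidates:
            if getattr(c, attr) == structure and c.estimable:
                if c.aic < best_aic - 1e-9:
                    best, best_aic = structure, c.aic
    return best


def select_model(candidates: list[CandidateModel],
                 response_name: str = "") -> SelectionOutcome:
    """Two-step structure selection, then treatment-effect extraction.

    Step 1 compares random structures by REML AIC under the interaction
    fixed structure; step 2 compares fixed structures by ML AIC holding
    the chosen random structure. Ties favor the simpler model. Slopes,
    the CO2 intercept shift and one-sided p-values come from the ML fit
    of the selected model.
    """
    step1 = [c for c in candidates
             if c.estimation == "REML" and c.fixed_structure == "interaction"]
    random = _pick(step1, ["none", "month_intercept"], "random_structure")
    if random is None:
        # fall back to main-effects REML fits if interaction was degenerate
        step1 = [c for c in candidates if c.estimation == "REML"]
        random = _pick(step1, ["none", "month_intercept"], "random_structure")
    if random is None:
        raise RuntimeError("all random-structure candidates non-estimable")

    step2 = [c for c in candidates
             if c.estimation == "ML" and c.random_structure == random]
    fixed = _pick(step2, ["main_effects", "interaction"], "fixed_structure")
    if fixed is None:
        raise RuntimeError("all fixed-structure candidates non-estimable")
    selected = next(c for c in step2 if c.fixed_structure == fixed)

    coefs = selected.coefficients
    slope_a, se_a = coefs["warming"]
    if fixed == "interaction":
        inter, se_i = coefs["warming:co2e"]
        slope_e = slope_a + inter
        se_e = float(np.hypot(se_a, se_i))  # conservative (ignores covariance)
    else:
        slope_e, se_e = slope_a, se_a
    co2_shift = coefs.get("co2e", (0.0, 0.0))[0]
    df_resid = selected.n - len(coefs)
    one_sided = "greater" if response_name in ONE_SIDED_RESPONSES else None
    pvals = {}
    for level, est, se in (("aCO2", slope_a, se_a), ("eCO2", slope_e, se_e)):
        if one_sided:
            pvals[level] = one_sided_p(est, se, df_resid, one_sided)
        else:
            pvals[level] = 2.0 * one_sided_p(abs(est), se, df_resid, "greater")
    return SelectionOutcome(
        response_name=response_name, selected=selected,
        all_candidates=candidates,
        warming_slope={"aCO2": slope_a, "eCO2": slope_e},
        warming_slope_se={"aCO2": se_a, "eCO2": se_e},
        co2_intercept_shift=float(co2_shift),
        intercept=coefs["Intercept"][0],
        one_sided_p=pvals, residual_df=df_resid)


def one_sided_p(estimate: float, se: float, df: int,
                direction: str = "greater") -> float:
    """One-sided t probability of ``estimate/se`` with ``df`` degrees of
    freedom; ``direction`` is "greater" or "less"."""
    if se <= 0:
        raise ValueError("se must be > 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    t = estimate / se
    return float(stats.t.sf(t, df) if direction == "greater"
                 else stats.t.cdf(t, df))


def anova_delta_tg(data: pd.DataFrame) -> pd.DataFrame:
    """Two-factor fixed-effects ANOVA for ΔMeanTg plot means.

    Warming enters as a 5-level factor (matching the grouped-bar view
    of the exceedance data) and CO2 as a 2-level factor; type-II sums
    of squares so unbalanced cells degrade gracefully (with a warning)
    rather than failing.
    """
    df = data[data["response_name"] == "delta_mean_tg"] \
        if "response_name" in data else data
    df = _prepare(df)
    for factor, levels in (("warming_offset_c", 2), ("co2_treatment", 2)):
        if df[factor].nunique() < levels:
            raise ValueError(f"ANOVA needs >= {levels} levels of {factor}")
    counts = df.groupby(["warming_offset_c", "co2_treatment"]).size()
    if counts.min() == 0 or counts.nunique() > 1:
        log.warning("unbalanced warming × CO2 cells; using type-II SS")
    model = smf.ols(
        "value ~ C(warming_offset_c) * C(co2_treatment)", df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(model, typ=2)
    return table
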
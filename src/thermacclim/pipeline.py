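"""End-to-end orchestration: curves → A–Ci fits → thermal → inference.

Stages are plain functions over DataFrames so they compose in scripts
and tests; :func:`run_pipeline` wires them together with validation,
per-record warning capture and a reproducibility manifest. Partial
failures (a curve that cannot be fitted, a tree whose temperature
response has no interior optimum) are logged and excluded — never
silently imputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import aci, inference, thermal
from .fvcb import KineticConstants
from .synthetic import MEASUREMENT_DATES, SyntheticConfig, generate_experiment

__all__ = ["RunConfig", "ResultsBundle", "run_pipeline", "validate_inputs",
           "stage_thermal"]

log = logging.getLogger(__name__)

EXPECTED_TLEAF = (15.0, 25.0, 32.5, 40.0, 45.0)


@dataclass
class RunConfig:
    """Paths, constants and options for one pipeline run."""

    aci_curves_path: str | Path | None = None
    climate_path: str | Path | None = None
    output_dir: str | Path = "results"
    # when no input paths are given, a synthetic experiment is generated
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0
    growth_ca: Mapping[str, float] = field(
        default_factory=lambda: {"aCO2": 400.0, "eCO2": 800.0})
    growth_ca_tolerance: float = 25.0
    hd: float = 200.0                     # kJ mol^-1
    window_days: int = 10
    daily_hours: tuple[int, int] = (9, 15)
    measurement_dates: Mapping[str, date] = field(
        default_factory=lambda: dict(MEASUREMENT_DATES))
    kinetics: KineticConstants = field(default_factory=KineticConstants)
    strict: bool = False


@dataclass
class ResultsBundle:
    """All pipeline outputs plus a manifest for reproduction."""

    aci_fits: pd.DataFrame
    tree_thermal: pd.DataFrame
    plot_means: pd.DataFrame
    regression_results: pd.DataFrame
    anova_delta_tg: pd.DataFrame
    manifest: dict
    warnings: list[str] = field(default_factory=list)

    def write(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.aci_fits.to_csv(out / "aci_fits.csv", index=False)
        self.tree_thermal.to_csv(out / "tree_thermal.csv", index=False)
        self.plot_means.to_csv(out / "plot_means.csv", index=False)
        self.regression_results.to_csv(out / "regression_results.csv",
                                       index=False)
        self.anova_delta_tg.to_csv(out / "anova_delta_tg.csv")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=str))


def validate_inputs(curves: pd.DataFrame,
                    climate: pd.DataFrame | None = None) -> list[dict]:
    """Structural and range checks on the input tables.

    Returns a report: a list of ``{"severity", "message", "row"}``
    entries; empty for a clean well-formed input.
    """
    report: list[dict] = []
    missing = set(aci.CURVE_COLUMNS) - set(curves.columns)
    if missing:
        report.append({"severity": "error", "row": None,
                       "message": f"missing columns: {sorted(missing)}"})
        return report
    bad = curves[~np.isfinite(
        curves[["ca_ppm", "ci_ppm", "a_umol_m2_s", "tleaf_c"]]).all(axis=1)]
    for i in bad.index:
        report.append({"severity": "error", "row": int(i),
                       "message": "non-finite numeric value"})
    out_of_range = curves[(curves.tleaf_c < -10) | (curves.tleaf_c > 50)]
    for i in out_of_range.index:
        report.append({"severity": "error", "row": int(i),
                       "message": f"tleaf_c={curves.loc[i, 'tleaf_c']} "
                                  "outside [-10, 50] °C"})
    for key, grp in curves.groupby(aci.CURVE_KEY):
        if len(grp) != 11:
            report.append({
                "severity": "warning", "row": None,
                "message": f"curve {key} has {len(grp)} steps, expected 11"})
    tree_key = [c for c in aci.CURVE_KEY if c != "tleaf_c"]
    for key, grp in curves.groupby(tree_key):
        temps = set(grp.tleaf_c.unique())
        missing_t = set(EXPECTED_TLEAF) - temps
        if missing_t:
            sev = "warning" if missing_t <= {45.0} else "warning"
            report.append({
                "severity": sev, "row": None,
                "message": f"tree {key} missing leaf temperatures "
                           f"{sorted(missing_t)}"})
    if climate is not None:
        need = {"plot_id", "timestamp", "air_temp_c"}
        if not need <= set(climate.columns):
            report.append({"severity": "error", "row": None,
                           "message": f"climate table missing "
                                      f"{sorted(need - set(climate.columns))}"})
    return report


TREE_KEY = ["plot_id", "species", "co2_treatment", "warming_offset_c",
            "tree_id", "month"]


def stage_thermal(aci_fits: pd.DataFrame, growth_a: pd.DataFrame,
                  climate: pd.DataFrame | None, config: RunConfig,
                  warnings_out: list[str] | None = None) -> pd.DataFrame:
    """Per tree × month thermal summaries.

    Fits the quadratic response to the growth-CO2 A series (ToptA,
    Aopt, b), the peaked Arrhenius function to the Vcmax and Jmax
    series (ToptV/EaV, ToptJ/EaJ), evaluates Ag and ΔMeanTg from the
    plot's pre-measurement daytime climate, and the A70 optimum from
    the per-temperature fits. Trees whose A(T) has no interior optimum
    are excluded with a warning.
    """
    sink = warnings_out if warnings_out is not None else []
    climate_cache: dict[tuple[str, str], thermal.ClimateWindowSummary] = {}
    fit_groups = dict(iter(aci_fits.groupby(TREE_KEY, sort=False))) \
        if len(aci_fits) else {}
    rows = []
    for key, ga in growth_a.groupby(TREE_KEY, sort=False):
        rec = dict(zip(TREE_KEY, key))
        fits = fit_groups.get(key, aci_fits.iloc[0:0])
        series = thermal.TemperatureSeries(
            tuple(ga.tleaf_c), tuple(ga.a_growth), "Anet")
        qfit = thermal.fit_quadratic_topt(series)
        if not qfit.converged:
            sink.append(f"{key}: no interior optimum in A(T); excluded")
            continue
        rec.update(topt_a=qfit.topt_a, aopt=qfit.aopt, b=qfit.b,
                   topt_a_sse=qfit.sse)

        if len(fits) >= 4:
            for qty, col in (("Vcmax", "vcmax"), ("Jmax", "jmax")):
                try:
                    afit = thermal.fit_peaked_arrhenius(
                        thermal.TemperatureSeries(
                            tuple(fits.tleaf_c), tuple(fits[col]), qty),
                        hd_fixed=config.hd)
                    suffix = "v" if qty == "Vcmax" else "j"
                    rec[f"topt_{suffix}"] = afit.topt
                    rec[f"ea_{suffix}"] = afit.ea
                    rec[f"kopt_{suffix}"] = afit.kopt
                except (thermal.InsufficientDataError,
                        thermal.NonConvergenceError) as err:
                    sink.append(f"{key}: {qty} Arrhenius fit failed: {err}")
            gca = config.growth_ca[rec["co2_treatment"]]
            try:
                _, a70fit = thermal.compute_a70_topt(fits, gca,
                                                     config.kinetics)
                if a70fit.converged:
                    rec["topt_a70"] = a70fit.topt_a
            except Exception as err:  # noqa: BLE001
                sink.append(f"{key}: A70 fit failed: {err}")

        if climate is not None:
            ckey = (rec["plot_id"], rec["month"])
            if ckey not in climate_cache:
                climate_cache[ckey] = thermal.summarize_climate(
                    climate[climate.plot_id == rec["plot_id"]],
                    config.measurement_dates[rec["month"]],
                    config.window_days, config.daily_hours,
                    plot_id=rec["plot_id"])
            summ = climate_cache[ckey]
            rec["mean_tg"] = summ.mean_t
            rec["max_tg"] = summ.max_t
            rec["a_g"] = thermal.compute_ag(qfit, summ.mean_t)
            rec["delta_mean_tg"] = thermal.compute_delta_mean_tg(summ, qfit)
        rows.append(rec)
    if not rows:
        raise RuntimeError("thermal stage produced no trees")
    return pd.DataFrame(rows)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute all stages and return (without writing) the results.

    With no input paths configured, a synthetic experiment is generated
    from ``config.synthetic`` and ``config.seed`` — the run is then a
    pure function of the config, and the manifest records everything
    needed to reproduce it bit-identically.
    """
    warnings_out: list[str] = []
    if config.aci_curves_path is None:
        exp = generate_experiment(config.synthetic, config.seed)
        curves, climate = exp["aci_curves"], exp["climate"]
    else:
        curves = pd.read_csv(config.aci_curves_path)
        climate = pd.read_csv(config.climate_path) \
            if config.climate_path else None

    report = validate_inputs(curves, climate)
    errors = [r for r in report if r["severity"] == "error"]
    if errors or (config.strict and report):
        raise ValueError(f"input validation failed: {report[:10]}")
    warnings_out += [r["message"] for r in report]

    aci_fits = aci.fit_curves_table(curves, config.kinetics)
    growth_a = aci.extract_growth_a_table(curves, dict(config.growth_ca),
                                          config.growth_ca_tolerance)
    tree_thermal = stage_thermal(aci_fits, growth_a, climate, config,
                                 warnings_out)
    plot_means = inference.aggregate_plot_means(tree_thermal)

    results = []
    for (species, resp), sub in plot_means.groupby(
            ["species", "response_name"], sort=False):
        if sub.value.notna().sum() < 8:
            warnings_out.append(f"{species}/{resp}: too few plot means; "
                                "skipped")
            continue
        try:
            outcome = inference.select_model(
                inference.fit_candidates(sub, resp), resp)
        except RuntimeError as err:
            warnings_out.append(f"{species}/{resp}: selection failed: {err}")
            continue
        results.append({
            "species": species,
            "response_name": resp,
            "random_structure": outcome.selected.random_structure,
            "fixed_structure": outcome.selected.fixed_structure,
            "intercept": outcome.intercept,
            "warming_slope_aco2": outcome.warming_slope["aCO2"],
            "warming_slope_eco2": outcome.warming_slope["eCO2"],
            "co2_intercept_shift": outcome.co2_intercept_shift,
            "p_aco2": outcome.one_sided_p["aCO2"],
            "p_eco2": outcome.one_sided_p["eCO2"],
            "aic": outcome.selected.aic, "aicc": outcome.selected.aicc,
        })
    regression = pd.DataFrame(results)

    anovas = []
    for species, sub in plot_means.groupby("species", sort=False):
        try:
            tab = inference.anova_delta_tg(sub)
            tab.insert(0, "species", species)
            anovas.append(tab)
        except (ValueError, KeyError) as err:
            warnings_out.append(f"{species}: ΔMeanTg ANOVA skipped: {err}")
    anova = pd.concat(anovas) if anovas else pd.DataFrame()

    manifest = {
        "config_hash": _config_hash(config), "seed": config.seed,
        "n_curves": int(curves.groupby(aci.CURVE_KEY).ngroups),
        "n_trees_fit": int(len(tree_thermal)),
        "n_warnings": len(warnings_out),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    for w in warnings_out:
        log.warning("%s", w)
    return ResultsBundle(aci_fits, tree_thermal, plot_means, regression,
                         anova, manifest, warnings_out)
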
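"""Per-tree temperature-response fitting and derived thermal quantities.

Three layers:

* nonlinear least-squares fitting of the peaked Arrhenius function to
  Vcmax(T) and Jmax(T) series with the deactivation energy Hd fixed
  (200 kJ mol^-1 by default) and multistart initialization;
* exact polynomial least squares for the quadratic temperature response
  of net photosynthesis, giving the thermal optimum ToptA, the rate at
  the optimum Aopt and the curvature b;
* climate-window summaries and the derived quantities built on the
  quadratic fit — net photosynthesis at growth temperature (Ag), the
  exceedance of the optimum by the growth temperature (ΔMeanTg), and
  the stomatal-variation-free optimum from A70 (net A recomputed at a
  fixed Ci/Ca of 0.7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .fvcb import (KineticConstants, PeakedArrheniusParams, QuadraticParams,
                   net_a_curve, peaked_arrhenius, quadratic_a)

__all__ = [
    "TemperatureSeries",
    "ArrheniusFitResult",
    "QuadraticFitResult",
    "ClimateWindowSummary",
    "InsufficientDataError",
    "NonConvergenceError",
    "fit_peaked_arrhenius",
    "fit_quadratic_topt",
    "summarize_climate",
    "compute_ag",
    "compute_delta_mean_tg",
    "compute_a70_topt",
]

log = logging.getLogger(__name__)

HD_DEFAULT = 200.0  # kJ mol^-1, fixed to avoid over-parameterization
TOPT_STARTS = (25.0, 30.0, 35.0)   # °C
EA_STARTS = (40.0, 60.0)           # kJ mol^-1


class InsufficientDataError(ValueError):
    """Too few points for the requested fit."""


class NonConvergenceError(RuntimeError):
    """No multistart attempt converged."""


class DegenerateFitError(ValueError):
    """Design matrix is singular (collinear temperatures)."""


@dataclass(frozen=True)
class TemperatureSeries:
    """A rate measured/derived at several leaf temperatures (°C)."""

    tleaf: tuple[float, ...]
    values: tuple[float, ...]
    quantity: str = "Anet"  # "Vcmax" | "Jmax" | "Anet"

    def __post_init__(self) -> None:
        object.__setattr__(self, "tleaf", tuple(float(t) for t in self.tleaf))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.tleaf) != len(self.values):
            raise ValueError("tleaf and values must have equal length")
        if len(set(self.tleaf)) < 3:
            raise InsufficientDataError("need >= 3 distinct temperatures")


@dataclass
class ArrheniusFitResult:
    """Peaked-Arrhenius fit with Hd held fixed."""

    kopt: float
    topt: float          # °C
    ea: float            # kJ mol^-1
    hd: float            # kJ mol^-1 (fixed)
    sse: float
    converged: bool
    topt_in_range: bool = True

    def params(self) -> PeakedArrheniusParams:
        return PeakedArrheniusParams(self.kopt, self.topt + 273.15,
                                     self.ea, self.hd)


@dataclass
class QuadraticFitResult:
    """Quadratic temperature-response fit of net photosynthesis."""

    aopt: float
    topt_a: float        # °C
    b: float
    sse: float
    converged: bool
    topt_in_range: bool = True

    def params(self) -> QuadraticParams:
        return QuadraticParams(self.aopt, self.topt_a, self.b)


@dataclass(frozen=True)
class ClimateWindowSummary:
    """Daytime air-temperature summary over a pre-measurement window."""

    plot_id: str
    window: tuple[date, date]          # [start, end) days
    daily_hours: tuple[int, int]       # [start, end) local hour
    mean_t: float                      # °C
    max_t: float                       # °C
    n_samples: int
    coverage_ok: bool


def _profiled_residuals(theta: np.ndarray, tk: np.ndarray, y: np.ndarray,
                        hd: float) -> tuple[np.ndarray, float]:
    """Residuals of the peaked Arrhenius model with kopt profiled out.

    For fixed (topt, ea) the model is linear in kopt, so the optimal
    kopt has the closed form (f·y)/(f·f) with f the unit-kopt shape.
    """
    topt_c, ea = theta
    params = PeakedArrheniusParams(1.0, topt_c + 273.15, ea, hd)
    shape = peaked_arrhenius(params, tk)
    denom = float(shape @ shape)
    kopt = float(shape @ y) / denom if denom > 0 else 0.0
    return kopt * shape - y, kopt


def fit_peaked_arrhenius(series: TemperatureSeries,
                         hd_fixed: float = HD_DEFAULT) -> ArrheniusFitResult:
    """Least-squares peaked-Arrhenius fit with fixed Hd and multistart.

    kopt is profiled linearly, leaving a 2-parameter (topt, ea)
    nonlinear problem started from every combination of
    topt ∈ {25, 30, 35} °C and ea ∈ {40, 60} kJ mol^-1 (kopt start is
    the largest observed value, implicit in the profiling); the
    converged solution with the lowest SSE is returned. Requires at
    least 4 points, all positive.
    """
    if len(series.tleaf) < 4:
        raise InsufficientDataError(
            f"peaked Arrhenius fit needs >= 4 points, got {len(series.tleaf)}")
    y = np.asarray(series.values)
    if np.any(y <= 0):
        raise ValueError("all series values must be > 0")
    tk = np.asarray(series.tleaf) + 273.15

    best = None
    diagnostics = []
    for topt0 in TOPT_STARTS:
        for ea0 in EA_STARTS:
            try:
                sol = least_squares(
                    lambda th: _profiled_residuals(th, tk, y, hd_fixed)[0],
                    x0=[topt0, ea0],
                    bounds=([-20.0, 1.0], [55.0, hd_fixed - 1.0]),
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception as err:  # noqa: BLE001 - diagnostic capture
                diagnostics.append((topt0, ea0, repr(err)))
                continue
            if not sol.success:
                diagnostics.append((topt0, ea0, sol.message))
                continue
            sse = float(2.0 * sol.cost)
            if best is None or sse < best[0]:
                best = (sse, sol.x)
    if best is None:
        raise NonConvergenceError(
            f"no start converged for {series.quantity}: {diagnostics}")
    sse, (topt_c, ea) = best
    _, kopt = _profiled_residuals(np.array([topt_c, ea]), tk, y, hd_fixed)
    in_range = 5.0 <= topt_c <= 50.0
    if not in_range:
        log.warning("fitted topt=%.1f°C outside [5, 50] for %s",
                    topt_c, series.quantity)
    return ArrheniusFitResult(kopt=float(kopt), topt=float(topt_c),
                              ea=float(ea), hd=hd_fixed, sse=sse,
                              converged=True, topt_in_range=in_range)


def fit_quadratic_topt(series: TemperatureSeries) -> QuadraticFitResult:
    """Exact polynomial least squares for A(T) = aopt − b·(T − topt_a)².

    Solved on the monomial basis a = c0 + c1·T + c2·T², then mapped back
    (b = −c2, topt_a = −c1/2c2, aopt = c0 − c1²/4c2). A non-negative c2
    means no interior optimum: the result is flagged unconverged and
    downstream analyses exclude the tree.
    """
    t = np.asarray(series.tleaf)
    y = np.asarray(series.values)
    X = np.column_stack([np.ones_like(t), t, t * t])
    if np.linalg.matrix_rank(X) < 3:
        raise DegenerateFitError("collinear temperature design")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    c0, c1, c2 = (float(c) for c in coef)
    sse = float(np.sum((y - X @ coef) ** 2))
    if c2 >= 0:
        return QuadraticFitResult(aopt=np.nan, topt_a=np.nan, b=max(-c2, 0.0),
                                  sse=sse, converged=False)
    b = -c2
    topt_a = -c1 / (2.0 * c2)
    aopt = c0 - c1 * c1 / (4.0 * c2)
    lo, hi = min(series.tleaf) - 10.0, max(series.tleaf) + 10.0
    in_range = lo <= topt_a <= hi
    if not in_range:
        log.warning("topt_a=%.1f°C outside measured range ±10°C", topt_a)
    return QuadraticFitResult(aopt=aopt, topt_a=topt_a, b=b, sse=sse,
                              converged=True, topt_in_range=in_range)


def summarize_climate(series: pd.DataFrame, measurement_date: date,
                      window_days: int = 10,
                      daily_hours: tuple[int, int] = (9, 15),
                      plot_id: str | None = None) -> ClimateWindowSummary:
    """Daytime mean/max air temperature over the pre-measurement window.

    ``series`` needs columns ``timestamp`` (datetime-like) and
    ``air_temp_c``. Retains samples whose local hour lies in
    [daily_hours[0], daily_hours[1]) on the ``window_days`` full days
    strictly before ``measurement_date``. Warns (via the summary's
    ``coverage_ok`` flag and the log) when under half the expected
    samples are present; raises ``ValueError`` for an empty window.
    """
    ts = pd.to_datetime(series["timestamp"])
    if not ts.is_monotonic_increasing:
        raise ValueError("climate timestamps must be strictly increasing")
    start = datetime.combine(measurement_date - timedelta(days=window_days),
                             time(0))
    end = datetime.combine(measurement_date, time(0))
    h0, h1 = daily_hours
    mask = (ts >= start) & (ts < end) & (ts.dt.hour >= h0) & (ts.dt.hour < h1)
    vals = series.loc[mask.to_numpy(), "air_temp_c"].to_numpy(dtype=float)
    if len(vals) == 0:
        raise ValueError(
            f"no climate samples in the {window_days}-day window before "
            f"{measurement_date}")
    # expected count assumes the series' native sampling interval
    step_h = max((ts.diff().dt.total_seconds().median() or 3600.0) / 3600.0,
                 1e-9)
    expected = window_days * (h1 - h0) / step_h
    coverage_ok = len(vals) >= 0.5 * expected
    if not coverage_ok:
        log.warning("climate window before %s has %d/%d expected samples",
                    measurement_date, len(vals), int(expected))
    pid = plot_id if plot_id is not None else str(
        series["plot_id"].iloc[0]) if "plot_id" in series else ""
    return ClimateWindowSummary(
        plot_id=pid,
        window=(measurement_date - timedelta(days=window_days),
                measurement_date),
        daily_hours=daily_hours, mean_t=float(np.mean(vals)),
        max_t=float(np.max(vals)), n_samples=len(vals),
        coverage_ok=coverage_ok)


def compute_ag(fit: QuadraticFitResult, t: float) -> float:
    """Net photosynthesis at a growth temperature via the quadratic fit.

    Negative values are returned as-is (net assimilation can be
    negative far from the optimum) with a log note.
    """
    if not fit.converged:
        raise ValueError("quadratic fit did not converge; cannot evaluate Ag")
    a = float(quadratic_a(fit.params(), t))
    if a < 0:
        log.info("Ag=%.2f < 0 at T=%.1f°C (topt_a=%.1f)", a, t, fit.topt_a)
    return a


def compute_delta_mean_tg(climate: ClimateWindowSummary,
                          fit: QuadraticFitResult) -> float:
    """ΔMeanTg = mean daytime growth temperature − ToptA (positive when
    the air is warmer than the photosynthetic optimum)."""
    if not fit.converged:
        raise ValueError("quadratic fit did not converge")
    return climate.mean_t - fit.topt_a


def compute_a70_topt(per_temperature_fits: pd.DataFrame, growth_ca: float,
                     constants: KineticConstants | None = None,
                     arrhenius_smoothed: tuple[ArrheniusFitResult,
                                               ArrheniusFitResult] | None = None,
                     ) -> tuple[pd.DataFrame, QuadraticFitResult]:
    """Thermal optimum of A70 — net A recomputed at Ci/Ca = 0.7.

    ``per_temperature_fits`` holds one row per leaf temperature with
    columns ``tleaf_c``, ``vcmax``, ``jmax``, ``rday`` and optionally
    ``tpu``; Ci is fixed at 0.7·growth Ca (280 ppm for 400, 560 for
    800), A70 = min(Ac, Aj, ATPU) per temperature, and the quadratic
    temperature response is fitted to the A70 series. When
    ``arrhenius_smoothed`` (Vcmax fit, Jmax fit) is given, capacities
    come from those fits instead of the raw per-temperature estimates.
    """
    constants = constants or KineticConstants()
    ci = 0.7 * growth_ca
    rows = []
    for r in per_temperature_fits.sort_values("tleaf_c").itertuples():
        tleaf = float(r.tleaf_c)
        if arrhenius_smoothed is not None:
            fit_v, fit_j = arrhenius_smoothed
            vcmax = float(peaked_arrhenius(fit_v.params(), tleaf + 273.15))
            jmax = float(peaked_arrhenius(fit_j.params(), tleaf + 273.15))
        else:
            vcmax, jmax = float(r.vcmax), float(r.jmax)
        tpu = getattr(r, "tpu", None)
        if tpu is None or (isinstance(tpu, float) and np.isnan(tpu)):
            tpu = np.inf  # ATPU branch skipped when TPU was not expressed
        a70 = float(net_a_curve(ci, vcmax, jmax, float(r.rday), tleaf,
                                constants, tpu=float(tpu)))
        rows.append({"tleaf_c": tleaf, "ci": ci, "a70": a70})
    table = pd.DataFrame(rows)
    series = TemperatureSeries(tuple(table.tleaf_c), tuple(table.a70), "Anet")
    return table, fit_quadratic_topt(series)
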
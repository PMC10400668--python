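"""Bilinear estimation of Vcmax, Jmax, Rday (and TPU) from A–Ci curves.

The bilinear method exploits the fact that, once the kinetic constants
are fixed at the measured leaf temperature, both limitation states of
the FvCB model are *linear* in transformed Ci:

    Ac = Vcmax · x1 − Rday,   x1 = (Ci − Γ*) / (Ci + Kc·(1 + O/Ko))
    Aj = (Jmax/4) · x2 − Rday, x2 = (Ci − Γ*) / (Ci + 2Γ*)

So for every admissible split of the Ci-sorted points into a low-Ci
(Rubisco-limited) and a high-Ci (RuBP-regeneration-limited) segment,
two linear regressions give candidate parameters; the split minimizing
the summed squared error of the reconstructed piecewise model
min(Ac, Aj) wins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .fvcb import KineticConstants

__all__ = [
    "ACiPoint",
    "ACiCurve",
    "ACiFit",
    "DegenerateCurveError",
    "FitFailureError",
    "MissingStepError",
    "fit_aci_bilinear",
    "extract_growth_a",
    "fit_curves_table",
]

log = logging.getLogger(__name__)

MIN_SEGMENT = 3          # minimum points per limitation segment
GROWTH_CA_TOL = 25.0     # ppm tolerance when matching the growth CO2 step


class DegenerateCurveError(ValueError):
    """Curve lacks the spread or point count needed for a bilinear fit."""


class FitFailureError(RuntimeError):
    """Bilinear fit produced nonphysical parameters."""


class MissingStepError(KeyError):
    """No measurement step matches the requested chamber CO2."""


@dataclass(frozen=True)
class ACiPoint:
    """One step of an A–Ci response curve."""

    step_index: int
    ca: float  # µmol mol^-1
    ci: float  # µmol mol^-1
    a: float   # µmol m^-2 s^-1

    def __post_init__(self) -> None:
        if not self.ca > 0:
            raise ValueError("ca must be > 0")
        if self.ci < 0:
            raise ValueError("ci must be >= 0")
        if self.ci >= self.ca + 50.0:
            raise ValueError(f"ci={self.ci} implausibly exceeds ca={self.ca}")


@dataclass(frozen=True)
class ACiCurve:
    """A–Ci response of one tree at one leaf temperature.

    Carries the full experimental metadata so downstream tables can be
    grouped by plot, species, treatment and campaign month.
    """

    plot_id: str
    species: str            # "tamarack" | "black_spruce"
    co2_treatment: str      # "aCO2" | "eCO2"
    warming_offset: float   # °C above ambient
    tree_id: str
    month: str              # "June" | "August"
    tleaf: float            # °C
    points: tuple[ACiPoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))

    @property
    def ci(self) -> np.ndarray:
        return np.array([p.ci for p in self.points])

    @property
    def a(self) -> np.ndarray:
        return np.array([p.a for p in self.points])

    def is_fittable(self) -> bool:
        """At least 6 points with 3 below Ci=300 and 3 above Ci=500."""
        ci = self.ci
        return (len(ci) >= 2 * MIN_SEGMENT
                and int(np.sum(ci < 300.0)) >= 3
                and int(np.sum(ci > 500.0)) >= 3)


@dataclass
class ACiFit:
    """Per-curve parameter estimates from the bilinear method."""

    vcmax: float
    jmax: float
    rday: float
    tpu: float | None
    transition_ci: float
    sse: float
    limitation_labels: tuple[str, ...]
    n_points: int
    rday_clamped: bool = False

    def __post_init__(self) -> None:
        if not (self.vcmax > 0 and self.jmax > 0):
            raise FitFailureError(
                f"nonphysical fit: vcmax={self.vcmax:.3g}, jmax={self.jmax:.3g}"
            )
        if self.rday < 0 or self.sse < 0:
            raise FitFailureError("rday and sse must be non-negative")


def _segment_fit(ci: np.ndarray, a: np.ndarray, split: int, gs: float,
                 km: float) -> tuple[float, float, float, float]:
    """Fit (vcmax, rday, jmax, sse) for one candidate transition index."""
    x1 = (ci - gs) / (ci + km)
    x2 = (ci - gs) / (ci + 2.0 * gs)
    lo, hi = slice(None, split), slice(split, None)

    # Rubisco segment: a = vcmax*x1 - rday
    X = np.column_stack([x1[lo], np.ones(split)])
    (vcmax, neg_rday), *_ = np.linalg.lstsq(X, a[lo], rcond=None)
    rday = -neg_rday
    clamped = rday < 0
    if clamped:
        rday = 0.0
        # refit slope through origin on (x1, a) once the intercept is pinned
        vcmax = float(x1[lo] @ a[lo] / (x1[lo] @ x1[lo]))

    # RuBP-regeneration segment: (a + rday) = (jmax/4)*x2, through origin
    y = a[hi] + rday
    jmax = 4.0 * float(x2[hi] @ y / (x2[hi] @ x2[hi]))

    # reconstruction SSE over all points; below Γ* the Rubisco branch
    # applies (the extrapolated Aj hyperbola undercuts Ac there, an
    # artifact of sub-compensation Ci, not a limitation change)
    ac_pred = vcmax * x1 - rday
    aj_pred = (jmax / 4.0) * x2 - rday
    pred = np.where(ci < gs, ac_pred, np.minimum(ac_pred, aj_pred))
    sse = float(np.sum((a - pred) ** 2))
    return float(vcmax), float(rday), jmax, sse


def fit_aci_bilinear(curve: ACiCurve, constants: KineticConstants | None = None,
                     min_segment: int = MIN_SEGMENT) -> ACiFit:
    """Fit one A–Ci curve by exhaustive bilinear changepoint search.

    Every transition index leaving at least ``min_segment`` points on
    each side is scored by the SSE of the reconstructed min(Ac, Aj)
    model over *all* points, and the best split retained. A negative
    Rday intercept is clamped to zero (with a warning) and the Rubisco
    slope refitted. TPU is reported only when the two highest-Ci steps
    fall more than one standard error below the Aj prediction.

    Raises :class:`DegenerateCurveError` for unfittable curves and
    :class:`FitFailureError` when the best split yields a nonpositive
    capacity.
    """
    constants = constants or KineticConstants()
    if not curve.is_fittable():
        raise DegenerateCurveError(
            f"curve {curve.plot_id}/{curve.tree_id} {curve.month} "
            f"@{curve.tleaf}°C: needs >= {2 * min_segment} points with 3 "
            "below Ci=300 and 3 above Ci=500"
        )
    order = np.argsort(curve.ci, kind="stable")
    ci, a = curve.ci[order], curve.a[order]
    gs = constants.gammastar(curve.tleaf)
    km = constants.km(curve.tleaf)

    best: tuple[float, int, float, float, float] | None = None
    for split in range(min_segment, len(ci) - min_segment + 1):
        vcmax, rday, jmax, sse = _segment_fit(ci, a, split, gs, km)
        if best is None or sse < best[0]:
            best = (sse, split, vcmax, rday, jmax)
    assert best is not None
    sse, split, vcmax, rday, jmax = best
    if vcmax <= 0 or jmax <= 0:
        raise FitFailureError(
            f"curve {curve.plot_id}/{curve.tree_id} @{curve.tleaf}°C: "
            f"best split gives vcmax={vcmax:.3g}, jmax={jmax:.3g} "
            f"(split={split}, sse={sse:.3g})"
        )
    clamped = False
    # re-derive clamp flag for reporting (clamping happened inside _segment_fit)
    X = np.column_stack([(ci - gs) / (ci + km), np.ones(len(ci))])
    coef, *_ = np.linalg.lstsq(X[:split], a[:split], rcond=None)
    if -coef[1] < 0:
        clamped = True
        log.warning("negative Rday clamped to 0 for %s/%s @%.1f°C",
                    curve.plot_id, curve.tree_id, curve.tleaf)

    transition_ci = 0.5 * (ci[split - 1] + ci[split])
    labels = tuple("Ac" if c <= transition_ci else "Aj" for c in ci)

    # TPU: flagged when the top two steps sit > 1 SE below the Aj line.
    tpu = None
    x2 = (ci - gs) / (ci + 2.0 * gs)
    aj_pred = (jmax / 4.0) * x2 - rday
    hi_resid = a[split:] - aj_pred[split:]
    n_hi = len(hi_resid)
    if n_hi > 2:
        se = float(np.std(hi_resid, ddof=1) / math.sqrt(2))
        shortfall = float(np.mean(aj_pred[-2:]) - np.mean(a[-2:]))
        if se > 0 and shortfall > se:
            tpu = (float(np.mean(a[-2:])) + rday) / 3.0

    return ACiFit(vcmax=vcmax, jmax=jmax, rday=rday, tpu=tpu,
                  transition_ci=float(transition_ci), sse=sse,
                  limitation_labels=labels, n_points=len(ci),
                  rday_clamped=clamped)


def extract_growth_a(curve: ACiCurve, growth_ca: float,
                     tolerance: float = GROWTH_CA_TOL) -> float:
    """Mean measured A over all steps within ``tolerance`` ppm of growth Ca.

    The measurement protocol visits Ca = 400 twice (before and after
    the low-CO2 ramp); both observations are used. Raises
    :class:`MissingStepError` when no step matches.
    """
    matches = [p.a for p in curve.points if abs(p.ca - growth_ca) <= tolerance]
    if not matches:
        raise MissingStepError(
            f"no step within {tolerance} ppm of Ca={growth_ca} for tree "
            f"{curve.plot_id}/{curve.tree_id} at tleaf={curve.tleaf}°C"
        )
    return float(np.mean(matches))


# ---------------------------------------------------------------------------
# Table-level drivers (CSV schema: one row per ACiPoint)

CURVE_KEY = ["plot_id", "species", "co2_treatment", "warming_offset_c",
             "tree_id", "month", "tleaf_c"]

CURVE_COLUMNS = CURVE_KEY + ["step_index", "ca_ppm", "ci_ppm", "a_umol_m2_s"]


def curves_from_table(df: pd.DataFrame) -> list[ACiCurve]:
    """Materialize :class:`ACiCurve` objects from the long-format table."""
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"aci_curves table missing columns: {sorted(missing)}")
    curves = []
    for key, grp in df.groupby(CURVE_KEY, sort=False):
        plot, species, co2, warm, tree, month, tleaf = key
        pts = tuple(
            ACiPoint(int(r.step_index), float(r.ca_ppm), float(r.ci_ppm),
                     float(r.a_umol_m2_s))
            for r in grp.sort_values("step_index").itertuples()
        )
        curves.append(ACiCurve(str(plot), str(species), str(co2), float(warm),
                               str(tree), str(month), float(tleaf), pts))
    return curves


def fit_curves_table(df: pd.DataFrame, constants: KineticConstants | None = None,
                     drop_failed_hot: bool = True) -> pd.DataFrame:
    """Fit every curve in a long-format table; one output row per curve.

    Failed fits at the hottest measurement temperature (45 °C curves are
    the noisiest) are dropped with a warning instead of aborting the
    tree; failures elsewhere propagate.
    """
    rows = []
    for curve in curves_from_table(df):
        try:
            fit = fit_aci_bilinear(curve, constants)
        except (DegenerateCurveError, FitFailureError) as err:
            if drop_failed_hot and curve.tleaf >= 45.0:
                log.warning("dropping 45°C curve: %s", err)
                continue
            raise
        rows.append({
            "plot_id": curve.plot_id, "species": curve.species,
            "co2_treatment": curve.co2_treatment,
            "warming_offset_c": curve.warming_offset,
            "tree_id": curve.tree_id, "month": curve.month,
            "tleaf_c": curve.tleaf, "vcmax": fit.vcmax, "jmax": fit.jmax,
            "rday": fit.rday, "tpu": fit.tpu,
            "transition_ci": fit.transition_ci, "sse": fit.sse,
            "n_points": fit.n_points, "rday_clamped": fit.rday_clamped,
        })
    return pd.DataFrame(rows)


def extract_growth_a_table(df: pd.DataFrame, growth_ca: dict[str, float],
                           tolerance: float = GROWTH_CA_TOL) -> pd.DataFrame:
    """Growth-CO2 net photosynthesis per curve, long format.

    ``growth_ca`` maps CO2 treatment labels to growth chamber CO2
    (e.g. {"aCO2": 400, "eCO2": 800}).
    """
    rows = []
    for curve in curves_from_table(df):
        a = extract_growth_a(curve, growth_ca[curve.co2_treatment], tolerance)
        rows.append({
            "plot_id": curve.plot_id, "species": curve.species,
            "co2_treatment": curve.co2_treatment,
            "warming_offset_c": curve.warming_offset,
            "tree_id": curve.tree_id, "month": curve.month,
            "tleaf_c": curve.tleaf, "a_growth": a,
        })
    return pd.DataFrame(rows)
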
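"""Synthetic warming × CO2 gas-exchange experiments with known truth.

Emulates the structure of a whole-ecosystem warming experiment: 10
plots (5 warming offsets × ambient/elevated CO2), 1–4 trees per plot,
two monthly campaigns, A–Ci curves at five leaf temperatures × the
11-step chamber CO2 sequence, and plot-level half-hourly air
temperature. Per-tree thermal truths follow configurable linear
acclimation relations (slope per °C warming, CO2 offsets) plus
plot/tree/month noise, and every truth is recorded so parameter
recovery can be scored exactly.

Curves are generated mechanistically: Vcmax(T) and Jmax(T) follow the
peaked Arrhenius function, Rday scales with a Q10 of 2, stomatal
behaviour is a constant Ci/Ca ratio (0.7), and A = min(Ac, Aj) plus
Gaussian noise. Because the thermal optimum of net photosynthesis is
an *emergent* property of the biochemistry, each tree's Arrhenius
parameters are calibrated (a batched damped-Newton root solve over the
optimum shift, activation-energy scale and respiratory fraction, then
an exact linear rescale) so that the quadratic temperature-response
fit of the noiseless A(T) at growth Ci reproduces the tree's
configured (ToptA, Aopt, b) truth exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .fvcb import GAS_CONSTANT, KineticConstants, PeakedArrheniusParams, \
    peaked_arrhenius

__all__ = [
    "LinearRelation",
    "SpeciesAcclimation",
    "SyntheticConfig",
    "generate_design",
    "generate_climate",
    "generate_tree_truth",
    "generate_aci_curves",
    "generate_experiment",
]

CA_SEQUENCE = (400.0, 300.0, 200.0, 50.0, 400.0, 500.0, 600.0, 800.0,
               1200.0, 1600.0, 2000.0)
TLEAF_SET = (15.0, 25.0, 32.5, 40.0, 45.0)
WARMING_LEVELS = (0.0, 2.25, 4.5, 6.75, 9.0)
MONTHS = ("June", "August")
MEASUREMENT_DATES = {"June": date(2017, 6, 24), "August": date(2017, 8, 22)}


@dataclass(frozen=True)
class LinearRelation:
    """truth = intercept + slope·warming + co2_offset·eCO2
    + co2_slope·eCO2·warming, all times co2_factor^eCO2."""

    intercept: float
    slope: float = 0.0
    co2_offset: float = 0.0
    co2_slope: float = 0.0
    co2_factor: float = 1.0

    def __call__(self, warming: float, eco2: bool) -> float:
        e = 1.0 if eco2 else 0.0
        lin = (self.intercept + self.slope * warming
               + self.co2_offset * e + self.co2_slope * e * warming)
        return lin * (self.co2_factor ** e)


@dataclass(frozen=True)
class SpeciesAcclimation:
    """Acclimation relations and biochemical baselines for one species."""

    topt_a: LinearRelation
    topt_v: LinearRelation
    topt_j: LinearRelation
    aopt: LinearRelation
    b: LinearRelation
    kopt_v_base: float = 60.0    # µmol m^-2 s^-1 before Aopt rescaling
    jmax_vcmax_ratio: float = 1.7
    ea_v_base: float = 50.0      # kJ mol^-1 before breadth calibration
    ea_j_base: float = 38.0
    rday_frac: float = 0.02      # Rday25 as a fraction of kopt_v


# Defaults follow the deciduous-conifer (tamarack) and evergreen-conifer
# (black spruce) acclimation patterns the generator is meant to emulate:
# ToptA rising 0.26 / 0.35 °C per °C warming, a +3 °C CO2 offset on
# tamarack ToptA only, biochemical optima rising faster than ToptA in
# spruce, an Aopt × CO2 interaction in spruce, and an 86 % elevation of
# the curvature b under elevated CO2 in tamarack.
TAMARACK = SpeciesAcclimation(
    topt_a=LinearRelation(23.2, 0.26, co2_offset=3.0),
    topt_v=LinearRelation(33.0, 0.35),
    topt_j=LinearRelation(31.8, 0.26),
    aopt=LinearRelation(7.9, 0.26, co2_offset=3.0),
    b=LinearRelation(0.020, co2_factor=1.86),
)
BLACK_SPRUCE = SpeciesAcclimation(
    topt_a=LinearRelation(23.3, 0.35),
    topt_v=LinearRelation(30.6, 0.44),
    topt_j=LinearRelation(28.6, 0.55),
    aopt=LinearRelation(6.4, 0.10, co2_offset=-0.1, co2_slope=0.44),
    b=LinearRelation(0.020),
    kopt_v_base=45.0,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic experiment."""

    warming_levels: tuple[float, ...] = WARMING_LEVELS
    co2_levels: Mapping[str, float] = field(
        default_factory=lambda: {"aCO2": 400.0, "eCO2": 800.0})
    trees_per_plot: int = 3
    months: tuple[str, ...] = MONTHS
    tleaf_set: tuple[float, ...] = TLEAF_SET
    ca_steps: tuple[float, ...] = CA_SEQUENCE
    species: tuple[str, ...] = ("tamarack", "black_spruce")
    acclimation: Mapping[str, SpeciesAcclimation] = field(
        default_factory=lambda: {"tamarack": TAMARACK,
                                 "black_spruce": BLACK_SPRUCE})
    # noise (the study conditions the generator emulates)
    sigma_a: float = 0.5         # µmol m^-2 s^-1, additive on each A point
    cv_capacity: float = 0.10    # relative, on capacities/Aopt/b truths
    sigma_topt_plot: float = 0.5  # °C, plot-level on thermal-optimum truths
    sigma_topt_tree: float = 0.3  # °C, tree-level on thermal-optimum truths
    month_offset: float = 0.5    # °C added to August topt truths vs June
    ci_ca_ratio: float = 0.7
    tpu_enabled: bool = False
    tpu_frac: float = 0.105      # TPU25 / kopt_v when enabled
    # climate
    # ambient daily mean chosen so the 4:00-20:30 daytime mean is ~19 °C,
    # the June value reported for the emulated site
    climate_mean: float = 19.0
    climate_amplitude: float = 6.0  # °C diurnal half-range (peak 15:00)
    climate_sigma: float = 1.5   # °C shared weather noise, half-hourly
    climate_start: date = date(2017, 6, 1)
    climate_end: date = date(2017, 9, 1)

    def __post_init__(self) -> None:
        if len(self.ca_steps) != 11:
            raise ValueError("ca_steps must have 11 entries")
        if len(set(self.warming_levels)) != len(self.warming_levels):
            raise ValueError("warming levels must be distinct")
        if not 1 <= self.trees_per_plot <= 4:
            raise ValueError("trees_per_plot must be in 1..4")
        for name in ("sigma_a", "cv_capacity", "sigma_topt_plot",
                     "sigma_topt_tree", "climate_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def generate_design(config: SyntheticConfig, seed: int) -> pd.DataFrame:
    """Plot/tree roster: one row per plot × species × tree × month."""
    rng = np.random.default_rng(seed)
    rows = []
    plot_num = 0
    for warm in config.warming_levels:
        for co2 in config.co2_levels:
            plot_num += 1
            plot_id = f"P{plot_num:02d}"
            for species in config.species:
                for t in range(1, config.trees_per_plot + 1):
                    for month in config.months:
                        rows.append({
                            "plot_id": plot_id, "species": species,
                            "co2_treatment": co2, "warming_offset_c": warm,
                            "tree_id": f"{species[:3]}T{t}", "month": month,
                        })
    del rng  # roster is deterministic; rng reserved for subsampling options
    return pd.DataFrame(rows)


def generate_climate(config: SyntheticConfig, seed: int) -> pd.DataFrame:
    """Half-hourly per-plot air temperature.

    T(plot, t) = ambient diurnal sinusoid + shared weather noise +
    the plot's warming offset. The weather term is shared across plots
    (one site), so pairwise daytime-mean differences equal the warming
    offsets exactly.
    """
    rng = np.random.default_rng(seed)
    times = pd.date_range(config.climate_start, config.climate_end,
                          freq="30min", inclusive="left")
    hours = times.hour + times.minute / 60.0
    ambient = (config.climate_mean
               + config.climate_amplitude
               * np.cos(2.0 * np.pi * (hours - 15.0) / 24.0))
    weather = rng.normal(0.0, config.climate_sigma, len(times)) \
        if config.climate_sigma > 0 else np.zeros(len(times))
    frames = []
    plot_num = 0
    for warm in config.warming_levels:
        for _co2 in config.co2_levels:
            plot_num += 1
            frames.append(pd.DataFrame({
                "plot_id": f"P{plot_num:02d}",
                "timestamp": times,
                "air_temp_c": ambient + weather + warm,
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Truth generation with emergent-consistency calibration


class _EmergentCalibrator:
    """Map (ToptA, Aopt, b) targets to FvCB generation parameters.

    Because the thermal optimum of net photosynthesis is emergent, the
    generator must invert the forward model: find biochemical
    parameters whose noiseless A(T) at growth Ci, when fitted with the
    quadratic temperature response at the measurement temperatures,
    lands exactly on the tree's configured (ToptA, Aopt, b) truth.

    Three knobs are used: a common shift ``d`` of the Vcmax/Jmax
    optima (controls ToptA), a common scale ``e`` on their activation
    energies and the 25 °C respiratory fraction ``rf = Rday25/Vcmax25``
    (together they control the relative curvature b/Aopt — respiration
    rising with a Q10 of 2 steepens the supra-optimal decline). ToptA
    and b/Aopt are solved by a batched damped Newton iteration on
    (d, log e) across a short ladder of rf values, with a scalar
    trust-region fallback for stragglers. Finally, because scaling
    Vcmax, Jmax and Rday jointly scales A(T) exactly linearly, a
    closed-form rescale pins Aopt (and hence b) to the target.
    """

    RF_LADDER = (1.0, 0.45, 2.2, 0.2, 4.5)
    TOL = 1e-8

    def __init__(self, tleaf_set: tuple[float, ...],
                 constants: KineticConstants) -> None:
        self.t = np.asarray(tleaf_set)
        self.tk = self.t + 273.15
        self.gs = constants.gammastar(self.t)
        self.km = constants.km(self.t)
        # pseudo-inverse of the quadratic design matrix, reused per eval
        X = np.column_stack([np.ones_like(self.t), self.t, self.t ** 2])
        self.q = np.linalg.pinv(X)

    @staticmethod
    def _peaked(kopt, topt_c, ea_kj, tk):
        # inlined peaked Arrhenius (Hd = 200 kJ mol^-1) for solver speed;
        # agreement with fvcb.peaked_arrhenius is covered by a unit test
        topt = topt_c + 273.15
        ea, hd = ea_kj * 1000.0, 200000.0
        x = (tk - topt) / (tk * GAS_CONSTANT * topt)
        return kopt * hd * np.exp(ea * x) / (hd - ea * (1.0 - np.exp(hd * x)))

    def _curve(self, ci, topt_v, ea_v, topt_j, ea_j, kopt_v, kopt_j, rday25):
        """A(T) rows; scalar args give shape (5,), column vectors (n, 5)."""
        vcmax = self._peaked(kopt_v, topt_v, ea_v, self.tk)
        jmax = self._peaked(kopt_j, topt_j, ea_j, self.tk)
        rday = rday25 * 2.0 ** ((self.t - 25.0) / 10.0)
        ac = vcmax * (ci - self.gs) / (ci + self.km) - rday
        aj = (jmax / 4.0) * (ci - self.gs) / (ci + 2.0 * self.gs) - rday
        return np.minimum(ac, aj)

    def _quad(self, a: np.ndarray):
        """(topt, aopt, b) of the quadratic LSQ fit; NaN where convex."""
        c0, c1, c2 = np.moveaxis(np.asarray(a) @ self.q.T, -1, 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            topt = np.where(c2 < 0, -c1 / (2 * c2), np.nan)
            aopt = np.where(c2 < 0, c0 - c1 * c1 / (4 * c2), np.nan)
            b = np.where(c2 < 0, -c2, np.nan)
        return topt, aopt, b

    def _resid_batch(self, d, loge, logrf, tgt):
        """Stacked residuals (2, n): ToptA error and 10·log curvature-ratio
        error; rows with no interior optimum get a large penalty."""
        e = np.exp(loge)
        a = self._curve(tgt["ci"][:, None], (tgt["tv0"] + d)[:, None],
                        (e * tgt["eav0"])[:, None],
                        (tgt["tj0"] + d)[:, None], (e * tgt["eaj0"])[:, None],
                        tgt["kv0"][:, None], tgt["kj0"][:, None],
                        (np.exp(logrf) * tgt["kv0"])[:, None])
        topt, aopt, b = self._quad(a)
        bad = ~np.isfinite(topt) | (aopt <= 0) | (b <= 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r1 = np.where(bad, 1e3, topt - tgt["topt_a"])
            r2 = np.where(bad, 1e3,
                          10.0 * np.log((b / aopt) / tgt["ratio"]))
        return np.vstack([r1, r2])

    def solve_batch(self, targets: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Calibrate all trees at once; returns generation parameters.

        ``targets`` holds per-tree arrays: topt_a, aopt, b, ci, tv0,
        tj0, kv0, kj0, eav0, eaj0, rf0, loge_hi.
        """
        tgt = dict(targets)
        tgt["ratio"] = tgt["b"] / tgt["aopt"]
        n = len(tgt["topt_a"])
        # heuristic respiratory fraction from the target relative curvature
        rf_pred = np.clip(7.5 * tgt["ratio"], 0.008, 0.13)

        d = np.full(n, np.nan)
        loge = np.full(n, np.nan)
        logrf = np.full(n, np.nan)
        done = np.zeros(n, dtype=bool)
        rf_cur = np.log(rf_pred)
        lo_rf, hi_rf = math.log(0.005), math.log(0.15)
        for _round in range(3):
            todo = ~done
            if not todo.any():
                break
            sub = {k: v[todo] for k, v in tgt.items()}
            rf_try = np.clip(rf_cur[todo], lo_rf, hi_rf)
            d_s, le_s, ok = self._newton(sub, rf_try)
            idx = np.flatnonzero(todo)
            d[idx], loge[idx], logrf[idx] = d_s, le_s, rf_try
            done[idx[ok]] = True
            # unconverged rows: nudge rf in the direction the curvature
            # residual demands (positive residual = too curved = less rday)
            if (~ok).any():
                r2 = self._resid_batch(d_s, le_s, rf_try, sub)[1]
                rf_cur[idx[~ok]] = rf_try[~ok] - 0.5 * np.sign(r2[~ok])
        # batched Levenberg-Marquardt over all three knobs polishes rows
        # stalled near min(Ac, Aj) branch-switch kinks; later passes restart
        # from fresh points instead of the stall
        da = tgt["topt_a"] - tgt["tv0"]
        for start in (None,
                      (da + 2.0, 0.8, math.log(0.06)),
                      (da + 9.0, -0.5, math.log(0.015))):
            todo = ~done
            if not todo.any():
                break
            sub = {k: v[todo] for k, v in tgt.items()}
            if start is None:
                x0 = (d[todo], loge[todo],
                      np.clip(logrf[todo], lo_rf, hi_rf))
            else:
                s0, s1, s2 = start
                x0 = (np.clip(np.broadcast_to(s0, len(tgt["topt_a"]))[todo],
                              -15.0, 15.0),
                      np.minimum(np.full(todo.sum(), s1), tgt["loge_hi"][todo]),
                      np.full(todo.sum(), s2))
            d_s, le_s, rf_s, ok = self._lm(sub, *map(np.array, x0))
            idx = np.flatnonzero(todo)
            d[idx], loge[idx], logrf[idx] = d_s, le_s, rf_s
            done[idx[ok]] = True
        for i in np.flatnonzero(~done):  # rare stragglers
            d[i], loge[i], logrf[i] = self._solve_scalar(
                {k: v[i] for k, v in tgt.items()},
                hint=(d[i], loge[i], logrf[i]))

        resid = np.abs(self._resid_batch(d, loge, logrf, tgt)).max(axis=0)
        e = np.exp(loge)
        a = self._curve(tgt["ci"][:, None], (tgt["tv0"] + d)[:, None],
                        (e * tgt["eav0"])[:, None], (tgt["tj0"] + d)[:, None],
                        (e * tgt["eaj0"])[:, None], tgt["kv0"][:, None],
                        tgt["kj0"][:, None],
                        (np.exp(logrf) * tgt["kv0"])[:, None])
        _, aopt_f, _ = self._quad(a)
        s = tgt["aopt"] / aopt_f  # exact linear rescale of all capacities
        return {
            "topt_v": tgt["tv0"] + d, "ea_v": e * tgt["eav0"],
            "topt_j": tgt["tj0"] + d, "ea_j": e * tgt["eaj0"],
            "kopt_v": s * tgt["kv0"], "kopt_j": s * tgt["kj0"],
            "rday25": s * np.exp(logrf) * tgt["kv0"],
            "calib_resid": resid,
        }

    def _newton(self, tgt: dict[str, np.ndarray], logrf: np.ndarray,
                max_iter: int = 40):
        """Damped Newton on (d, log e) with rf fixed, all rows at once.

        Starts from a coarse grid presolve of the optimum-shift d (the
        emergent ToptA is strongly monotone in d), then iterates a
        finite-difference Newton step with backtracking halving.
        """
        lo_e, hi_e = -2.0, tgt["loge_hi"]
        loge = np.zeros_like(tgt["topt_a"])
        # presolve d on a grid: pick the grid point with the smallest
        # absolute ToptA residual per row
        grid = np.arange(-10.0, 15.1, 1.25)
        r1 = np.stack([np.abs(self._resid_batch(
            np.full_like(loge, g), loge, logrf, tgt)[0]) for g in grid])
        d = grid[np.argmin(r1, axis=0)]

        h = 1e-6
        r = self._resid_batch(d, loge, logrf, tgt)
        for _ in range(max_iter):
            err = np.abs(r).max(axis=0)
            active = err > self.TOL
            if not active.any():
                break
            # finite-difference Jacobian, batched 2x2 solve
            rd = self._resid_batch(d + h, loge, logrf, tgt)
            re = self._resid_batch(d, loge + h, logrf, tgt)
            j11, j12 = (rd[0] - r[0]) / h, (re[0] - r[0]) / h
            j21, j22 = (rd[1] - r[1]) / h, (re[1] - r[1]) / h
            det = j11 * j22 - j12 * j21
            det = np.where(np.abs(det) < 1e-12, np.nan, det)
            step_d = np.clip(np.nan_to_num(-(j22 * r[0] - j12 * r[1]) / det),
                             -4.0, 4.0)
            step_e = np.clip(np.nan_to_num(-(j11 * r[1] - j21 * r[0]) / det),
                             -0.6, 0.6)
            # backtracking: halve the step until the residual norm drops
            scale = np.where(active, 1.0, 0.0)
            d_new, e_new = d.copy(), loge.copy()
            r_new = r.copy()
            improved = ~active
            for _bt in range(7):
                trial_mask = active & ~improved
                if not trial_mask.any():
                    break
                d_try = np.clip(d + scale * step_d, -15.0, 15.0)
                e_try = np.clip(loge + scale * step_e, lo_e, hi_e)
                r_try = self._resid_batch(d_try, e_try, logrf, tgt)
                better = trial_mask & (np.abs(r_try).max(axis=0) < err)
                d_new = np.where(better, d_try, d_new)
                e_new = np.where(better, e_try, e_new)
                r_new = np.where(better, r_try, r_new)
                improved |= better
                scale = np.where(improved, scale, scale / 2.0)
            if not (improved & active).any():
                break  # stalled everywhere that still matters
            d, loge, r = d_new, e_new, r_new
        return d, loge, np.abs(r).max(axis=0) <= self.TOL

    def _lm(self, tgt: dict[str, np.ndarray], d: np.ndarray,
            loge: np.ndarray, logrf: np.ndarray, max_iter: int = 35):
        """Batched damped Gauss-Newton (minimum-norm step) on all 3 knobs."""
        lo = np.array([-15.0, -2.0, math.log(0.005)])
        hi_e = tgt["loge_hi"]
        hi_rf = math.log(0.15)
        lam = np.full_like(d, 1e-2)
        h = 1e-6
        r = self._resid_batch(d, loge, logrf, tgt)
        for _ in range(max_iter):
            err = np.abs(r).max(axis=0)
            active = err > self.TOL
            if not active.any():
                break
            rd = self._resid_batch(d + h, loge, logrf, tgt)
            re = self._resid_batch(d, loge + h, logrf, tgt)
            rr = self._resid_batch(d, loge, logrf + h, tgt)
            J = np.stack([(rd - r) / h, (re - r) / h, (rr - r) / h])  # (3,2,n)
            improved = ~active
            for _try in range(6):
                mask = active & ~improved
                if not mask.any():
                    break
                # step = J^T (J J^T + lam I)^-1 (-r), J is (2,3) per row
                g11 = (J[:, 0] ** 2).sum(axis=0) + lam
                g22 = (J[:, 1] ** 2).sum(axis=0) + lam
                g12 = (J[:, 0] * J[:, 1]).sum(axis=0)
                det = g11 * g22 - g12 ** 2
                w1 = (-(g22 * r[0] - g12 * r[1])) / det
                w2 = (-(g11 * r[1] - g12 * r[0])) / det
                sd = J[0, 0] * w1 + J[0, 1] * w2
                se = J[1, 0] * w1 + J[1, 1] * w2
                sr = J[2, 0] * w1 + J[2, 1] * w2
                d_try = np.clip(d + sd, lo[0], 15.0)
                e_try = np.clip(loge + se, lo[1], hi_e)
                rf_try = np.clip(logrf + sr, lo[2], hi_rf)
                r_try = self._resid_batch(d_try, e_try, rf_try, tgt)
                better = mask & (np.abs(r_try).max(axis=0) < err)
                d = np.where(better, d_try, d)
                loge = np.where(better, e_try, loge)
                logrf = np.where(better, rf_try, logrf)
                r = np.where(better, r_try, r)
                lam = np.where(better, np.maximum(lam / 3.0, 1e-8),
                               np.where(mask, np.minimum(lam * 8.0, 1e7),
                                        lam))
                improved |= better
            if not (improved & active).any():
                break
        return d, loge, logrf, np.abs(r).max(axis=0) <= self.TOL

    def _solve_scalar(self, tgt: dict[str, float],
                      hint: tuple[float, float, float] | None = None):
        """Trust-region fallback over all three knobs for one tree."""
        tgt1 = {k: np.atleast_1d(np.asarray(v, dtype=float))
                for k, v in tgt.items()}

        def resid(theta):
            return self._resid_batch(theta[0], theta[1],
                                     np.asarray([theta[2]]), tgt1)[:, 0]

        da = float(tgt["topt_a"] - tgt["tv0"])
        starts = [[da + 6.0, 0.0, math.log(0.03)],
                  [da + 2.0, 0.8, math.log(0.06)],
                  [da + 9.0, -0.5, math.log(0.015)]]
        if hint is not None and all(map(math.isfinite, hint)):
            starts.insert(0, [float(np.clip(hint[0], -14.9, 14.9)),
                              float(np.clip(hint[1], -1.99,
                                            tgt["loge_hi"] - 1e-6)),
                              float(np.clip(hint[2], math.log(0.0051),
                                            math.log(0.149)))])
        best = None
        for x0 in starts:
            sol = least_squares(
                resid, x0=x0,
                bounds=([-15.0, -2.0, math.log(0.005)],
                        [15.0, float(tgt["loge_hi"]), math.log(0.15)]),
                xtol=1e-11, ftol=1e-11)
            if best is None or sol.cost < best.cost:
                best = sol
            if sol.cost < 1e-16:
                break
        return best.x


def generate_tree_truth(config: SyntheticConfig, roster: pd.DataFrame,
                        seed: int,
                        constants: KineticConstants | None = None,
                        ) -> pd.DataFrame:
    """Per tree × month true thermal parameters.

    Thermal-optimum truths get additive plot-level and tree-level
    Gaussian noise plus the month offset; Aopt and b truths get
    multiplicative (lognormal) noise with coefficient of variation
    ``cv_capacity`` (half that at the plot level). The biochemical
    generation parameters are then calibrated so the emergent
    quadratic-fit (ToptA, Aopt, b) of the noiseless curve equals the
    recorded truth.
    """
    constants = constants or KineticConstants()
    rng = np.random.default_rng(seed)
    calib = _EmergentCalibrator(config.tleaf_set, constants)
    cv_p = config.cv_capacity / 2.0

    plot_noise: dict[tuple[str, str], dict[str, float]] = {}
    tree_noise: dict[tuple[str, str, str], dict[str, float]] = {}
    rows = []
    for r in roster.itertuples():
        sp = config.acclimation[r.species]
        eco2 = r.co2_treatment == "eCO2"
        pkey = (r.plot_id, r.species)
        if pkey not in plot_noise:
            plot_noise[pkey] = {
                "topt": rng.normal(0.0, config.sigma_topt_plot),
                "aopt": rng.normal(0.0, cv_p),
                "b": rng.normal(0.0, cv_p),
            }
        tkey = (r.plot_id, r.species, r.tree_id)
        if tkey not in tree_noise:
            tree_noise[tkey] = {
                "topt": rng.normal(0.0, config.sigma_topt_tree),
                "aopt": rng.normal(0.0, config.cv_capacity),
                "b": rng.normal(0.0, config.cv_capacity),
            }
        pn, tn = plot_noise[pkey], tree_noise[tkey]
        dmonth = config.month_offset if r.month == "August" else 0.0
        dtopt = dmonth + pn["topt"] + tn["topt"]

        topt_a = sp.topt_a(r.warming_offset_c, eco2) + dtopt
        aopt = sp.aopt(r.warming_offset_c, eco2) \
            * math.exp(pn["aopt"] + tn["aopt"])
        b = sp.b(r.warming_offset_c, eco2) * math.exp(pn["b"] + tn["b"])
        if topt_a < 5.0 or aopt <= 0:
            raise ValueError(
                f"acclimation relations give nonphysical truth "
                f"(topt_a={topt_a:.1f}, aopt={aopt:.2f}) for {r.plot_id}")
        rows.append({
            "plot_id": r.plot_id, "species": r.species,
            "co2_treatment": r.co2_treatment,
            "warming_offset_c": r.warming_offset_c,
            "tree_id": r.tree_id, "month": r.month,
            "topt_a": topt_a, "aopt": aopt, "b": b,
            "_tv0": sp.topt_v(r.warming_offset_c, eco2) + dtopt,
            "_tj0": sp.topt_j(r.warming_offset_c, eco2) + dtopt,
            "_kv0": sp.kopt_v_base,
            "_kj0": sp.jmax_vcmax_ratio * sp.kopt_v_base,
            "_eav0": sp.ea_v_base, "_eaj0": sp.ea_j_base,
            "_loge_hi": math.log(199.0 / max(sp.ea_v_base, sp.ea_j_base)),
            "_ci": config.ci_ca_ratio * config.co2_levels[r.co2_treatment],
        })
    df = pd.DataFrame(rows)
    sol = calib.solve_batch({
        "topt_a": df.topt_a.to_numpy(), "aopt": df.aopt.to_numpy(),
        "b": df.b.to_numpy(), "ci": df._ci.to_numpy(),
        "tv0": df._tv0.to_numpy(), "tj0": df._tj0.to_numpy(),
        "kv0": df._kv0.to_numpy(), "kj0": df._kj0.to_numpy(),
        "eav0": df._eav0.to_numpy(), "eaj0": df._eaj0.to_numpy(),
        "loge_hi": df._loge_hi.to_numpy(),
    })
    df = df.drop(columns=[c for c in df.columns if c.startswith("_")])
    for key, arr in sol.items():
        df[key] = arr
    df["tpu25"] = config.tpu_frac * df["kopt_v"] if config.tpu_enabled \
        else np.nan
    return df


def generate_aci_curves(truth: pd.DataFrame, config: SyntheticConfig,
                        seed: int,
                        constants: KineticConstants | None = None,
                        ) -> pd.DataFrame:
    """Noisy A–Ci curves (long format) from the truth ledger.

    For each tree × month × leaf temperature: capacities follow the
    tree's peaked Arrhenius truth, Rday scales from 25 °C with Q10 = 2,
    Ci = ci_ca_ratio · Ca at every step, and A gets additive Gaussian
    noise with standard deviation ``sigma_a``.
    """
    constants = constants or KineticConstants()
    rng = np.random.default_rng(seed)
    t = np.asarray(config.tleaf_set)
    tk = t + 273.15
    gs = constants.gammastar(t)
    km = constants.km(t)
    ca = np.asarray(config.ca_steps)
    steps = np.arange(1, len(ca) + 1)

    frames = []
    for r in truth.itertuples():
        vcmax = peaked_arrhenius(
            PeakedArrheniusParams(r.kopt_v, r.topt_v + 273.15, r.ea_v), tk)
        jmax = peaked_arrhenius(
            PeakedArrheniusParams(r.kopt_j, r.topt_j + 273.15, r.ea_j), tk)
        rday = r.rday25 * 2.0 ** ((t - 25.0) / 10.0)
        ci = config.ci_ca_ratio * ca
        # grids: temperatures along axis 0, CO2 steps along axis 1
        ac = vcmax[:, None] * (ci - gs[:, None]) / (ci + km[:, None]) \
            - rday[:, None]
        aj = (jmax[:, None] / 4.0) * (ci - gs[:, None]) \
            / (ci + 2.0 * gs[:, None]) - rday[:, None]
        # Below Γ* the extrapolated RuBP-regeneration hyperbola dips under
        # the Rubisco branch — a mathematical artifact, not a limitation
        # change; leaves at sub-compensation Ci are Rubisco-limited, so the
        # two-segment convention (Ac below the branch crossing) applies.
        a = np.where(ci < gs[:, None], ac, np.minimum(ac, aj))
        if config.tpu_enabled and np.isfinite(r.tpu25):
            a = np.minimum(a, 3.0 * r.tpu25)
        if config.sigma_a > 0:
            a = a + rng.normal(0.0, config.sigma_a, a.shape)
        nt, ns = a.shape
        frames.append(pd.DataFrame({
            "plot_id": r.plot_id, "species": r.species,
            "co2_treatment": r.co2_treatment,
            "warming_offset_c": r.warming_offset_c,
            "tree_id": r.tree_id, "month": r.month,
            "tleaf_c": np.repeat(t, ns),
            "step_index": np.tile(steps, nt),
            "ca_ppm": np.tile(ca, nt),
            "ci_ppm": np.tile(ci, nt),
            "a_umol_m2_s": a.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def generate_experiment(config: SyntheticConfig, seed: int,
                        constants: KineticConstants | None = None,
                        ) -> dict[str, pd.DataFrame]:
    """Generate a complete experiment: design, climate, truth, curves.

    All outputs are a pure function of (config, seed); sub-seeds are
    spawned deterministically for each stage.
    """
    ss = np.random.SeedSequence(seed)
    s_design, s_climate, s_truth, s_curves = ss.generate_state(4)
    roster = generate_design(config, int(s_design))
    climate = generate_climate(config, int(s_climate))
    truth = generate_tree_truth(config, roster, int(s_truth), constants)
    curves = generate_aci_curves(truth, config, int(s_curves), constants)
    return {"design": roster, "climate": climate, "truth": truth,
            "aci_curves": curves}
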
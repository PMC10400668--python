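"""Farquhar–von Caemmerer–Berry (FvCB) forward model and temperature responses.

This module is the deterministic core of the package: steady-state C3
net assimilation as the minimum of the Rubisco-limited (Ac),
RuBP-regeneration-limited (Aj) and triose-phosphate-use-limited (ATPU)
rates, plus the two temperature-response functions used throughout the
analysis — a peaked (modified) Arrhenius function for the biochemical
capacities Vcmax and Jmax, and a quadratic for the temperature response
of net photosynthesis.

All rates are µmol CO2 m^-2 s^-1. CO2 mole fractions (Ci, Ca, Γ*, Kc)
are µmol mol^-1; O2 and Ko are mmol mol^-1. Activation/deactivation
energies of the peaked Arrhenius function are carried in kJ mol^-1 and
converted to J mol^-1 internally (the gas constant R is 8.314
J mol^-1 K^-1); the kinetic-constant scalings use J mol^-1 directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "T25_K",
    "KineticConstants",
    "PeakedArrheniusParams",
    "QuadraticParams",
    "FvCBState",
    "arrhenius_scaled",
    "peaked_arrhenius",
    "ac_rate",
    "aj_rate",
    "atpu_rate",
    "net_a",
    "quadratic_a",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
T25_K = 298.15  # K

ArrayLike = Union[float, np.ndarray]


class ParameterizationError(ValueError):
    """A parameter set violates a structural requirement of a model."""


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco/photorespiration kinetics and their Arrhenius scalings.

    Defaults are the Bernacchi in-vivo values conventionally used for
    Ci-based ("apparent") A–Ci fitting: Γ*=42.75 µmol mol^-1,
    Kc=404.9 µmol mol^-1, Ko=278.4 mmol mol^-1 at 25 °C, with
    activation energies 37 830, 79 430 and 36 380 J mol^-1, and an
    intercellular O2 of 210 mmol mol^-1.
    """

    gammastar25: float = 42.75   # µmol mol^-1
    kc25: float = 404.9          # µmol mol^-1
    ko25: float = 278.4          # mmol mol^-1
    ea_gammastar: float = 37830.0  # J mol^-1
    ea_kc: float = 79430.0         # J mol^-1
    ea_ko: float = 36380.0         # J mol^-1
    oxygen: float = 210.0          # mmol mol^-1
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        for name in ("gammastar25", "kc25", "ko25", "ea_gammastar",
                     "ea_kc", "ea_ko", "oxygen", "gas_constant"):
            if not getattr(self, name) > 0:
                raise ValueError(f"KineticConstants.{name} must be > 0")

    def gammastar(self, tleaf: ArrayLike) -> ArrayLike:
        """Γ* (µmol mol^-1) at a leaf temperature in °C."""
        return arrhenius_scaled(self.gammastar25, self.ea_gammastar, tleaf, self)

    def kc(self, tleaf: ArrayLike) -> ArrayLike:
        """Kc (µmol mol^-1) at a leaf temperature in °C."""
        return arrhenius_scaled(self.kc25, self.ea_kc, tleaf, self)

    def ko(self, tleaf: ArrayLike) -> ArrayLike:
        """Ko (mmol mol^-1) at a leaf temperature in °C."""
        return arrhenius_scaled(self.ko25, self.ea_ko, tleaf, self)

    def km(self, tleaf: ArrayLike) -> ArrayLike:
        """Effective Michaelis constant Kc·(1 + O/Ko) at tleaf (µmol mol^-1)."""
        return self.kc(tleaf) * (1.0 + self.oxygen / self.ko(tleaf))


@dataclass(frozen=True)
class PeakedArrheniusParams:
    """Parameters of the peaked Arrhenius temperature response.

    kopt is the process rate at the optimum (µmol m^-2 s^-1), topt the
    optimum temperature in Kelvin, ea and hd the activation and
    deactivation energies in kJ mol^-1. The function only has an
    interior peak when 0 < ea < hd.
    """

    kopt: float
    topt: float  # K
    ea: float    # kJ mol^-1
    hd: float = 200.0  # kJ mol^-1

    def __post_init__(self) -> None:
        if not self.kopt > 0:
            raise ValueError("kopt must be > 0")
        if not (250.0 <= self.topt <= 330.0):
            raise ValueError(f"topt={self.topt} K outside 250-330 K")
        if not self.ea > 0:
            raise ValueError("ea must be > 0")
        if self.hd <= self.ea:
            raise ParameterizationError(
                f"hd={self.hd} must exceed ea={self.ea}: the response loses its peak"
            )


@dataclass(frozen=True)
class QuadraticParams:
    """Quadratic (parabolic) temperature response of net photosynthesis.

    A(T) = aopt - b·(T - topt_a)^2, with aopt the rate at the thermal
    optimum topt_a (°C) and b (µmol m^-2 s^-1 °C^-2) the curvature: a
    larger b means a narrower, more temperature-sensitive response.
    """

    aopt: float
    topt_a: float  # °C
    b: float       # µmol m^-2 s^-1 °C^-2

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError("b must be >= 0")


@dataclass(frozen=True)
class FvCBState:
    """Point evaluation state for the FvCB model at one leaf temperature.

    vcmax, jmax, rday and tpu are the values *at* tleaf (not at 25 °C);
    temperature scaling of the capacities happens upstream.
    """

    ci: float      # µmol mol^-1
    vcmax: float   # µmol m^-2 s^-1
    jmax: float    # µmol m^-2 s^-1
    rday: float    # µmol m^-2 s^-1
    tleaf: float   # °C
    tpu: float = math.inf  # µmol m^-2 s^-1; inf disables the TPU cap

    def __post_init__(self) -> None:
        if self.ci < 0:
            raise ValueError("ci must be >= 0")
        if not (self.vcmax > 0 and self.jmax > 0 and self.tpu > 0):
            raise ValueError("vcmax, jmax, tpu must be > 0")
        if self.rday < 0:
            raise ValueError("rday must be >= 0")


def _check_finite(**kwargs: ArrayLike) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"non-finite input {name}={value!r}")


def arrhenius_scaled(k25: ArrayLike, ea: float, tleaf: ArrayLike,
                     constants: KineticConstants | None = None) -> ArrayLike:
    """Scale a 25 °C value to ``tleaf`` with a (non-peaked) Arrhenius law.

    k(T) = k25 · exp[ ea·(Tk − 298.15) / (298.15·R·Tk) ], Tk in Kelvin,
    ea in J mol^-1. Used for Γ*, Kc and Ko.
    """
    _check_finite(k25=k25, ea=ea, tleaf=tleaf)
    if np.any(np.asarray(tleaf) < -10.0) or np.any(np.asarray(tleaf) > 60.0):
        raise ValueError(f"tleaf={tleaf!r} outside plausible range [-10, 60] °C")
    r = constants.gas_constant if constants is not None else GAS_CONSTANT
    tk = np.asarray(tleaf, dtype=float) + 273.15
    out = k25 * np.exp(ea * (tk - T25_K) / (T25_K * r * tk))
    return float(out) if np.ndim(out) == 0 else out


def peaked_arrhenius(params: PeakedArrheniusParams, tk: ArrayLike) -> ArrayLike:
    """Peaked (modified) Arrhenius rate at absolute temperature ``tk`` (K).

    f(Tk) = kopt · Hd·exp[Ea·(Tk−Topt)/(Tk·R·Topt)]
                 / ( Hd − Ea·(1 − exp[Hd·(Tk−Topt)/(Tk·R·Topt)]) )

    with Ea < Hd so the rate peaks exactly at Topt, where f = kopt.
    """
    _check_finite(tk=tk)
    tk = np.asarray(tk, dtype=float)
    if np.any(tk <= 0):
        raise ValueError("tk must be positive (Kelvin)")
    ea = params.ea * 1000.0  # kJ -> J
    hd = params.hd * 1000.0
    x = (tk - params.topt) / (tk * GAS_CONSTANT * params.topt)
    num = hd * np.exp(ea * x)
    den = hd - ea * (1.0 - np.exp(hd * x))
    out = params.kopt * num / den
    return float(out) if np.ndim(out) == 0 else out


def ac_rate(state: FvCBState, constants: KineticConstants) -> float:
    """Rubisco-limited net rate Ac at the state's leaf temperature.

    Ac = Vcmax·(Ci − Γ*) / [Ci + Kc·(1 + O/Ko)] − Rday, with Γ*, Kc and
    Ko evaluated at tleaf.
    """
    gs = constants.gammastar(state.tleaf)
    km = constants.km(state.tleaf)
    return state.vcmax * (state.ci - gs) / (state.ci + km) - state.rday


def aj_rate(state: FvCBState, constants: KineticConstants) -> float:
    """RuBP-regeneration-limited net rate Aj.

    Aj = (Jmax/4)·(Ci − Γ*)/(Ci + 2Γ*) − Rday at saturating light,
    where the electron-transport rate equals Jmax.
    """
    gs = constants.gammastar(state.tleaf)
    return (state.jmax / 4.0) * (state.ci - gs) / (state.ci + 2.0 * gs) - state.rday


def atpu_rate(state: FvCBState, tpu_net: bool = False) -> float:
    """Triose-phosphate-use-limited rate, ATPU = 3·TPU.

    The conventional TPU cap is a gross rate independent of Ci and
    temperature; ``tpu_net=True`` subtracts Rday for users who want the
    three limitation states on a common net basis.
    """
    out = 3.0 * state.tpu
    if tpu_net:
        out -= state.rday
    return out


def net_a(state: FvCBState, constants: KineticConstants,
          tpu_net: bool = False) -> tuple[float, str]:
    """Net assimilation A = min(Ac, Aj, ATPU) and its limitation label.

    Ties are resolved in the priority order Ac > Aj > ATPU (the first
    state attaining the minimum is reported).
    """
    rates = (
        ("Ac", ac_rate(state, constants)),
        ("Aj", aj_rate(state, constants)),
        ("ATPU", atpu_rate(state, tpu_net=tpu_net)),
    )
    label, value = min(rates, key=lambda kv: kv[1])
    for lab, val in rates:  # enforce tie-break priority on exact ties
        if val == value:
            return val, lab
    return value, label  # pragma: no cover


def quadratic_a(params: QuadraticParams, t: ArrayLike) -> ArrayLike:
    """Quadratic net-photosynthesis temperature response A(T).

    A = aopt − b·(T − topt_a)^2 with T in °C.
    """
    t = np.asarray(t, dtype=float)
    out = params.aopt - params.b * (t - params.topt_a) ** 2
    return float(out) if np.ndim(out) == 0 else out


def net_a_curve(ci: ArrayLike, vcmax: float, jmax: float, rday: float,
                tleaf: float, constants: KineticConstants,
                tpu: float = math.inf, tpu_net: bool = False) -> np.ndarray:
    """Vectorized min(Ac, Aj, ATPU) over an array of Ci values.

    Convenience wrapper used by the A–Ci fitter and the synthetic-data
    generator; identical arithmetic to :func:`net_a`.
    """
    ci = np.asarray(ci, dtype=float)
    gs = constants.gammastar(tleaf)
    km = constants.km(tleaf)
    ac = vcmax * (ci - gs) / (ci + km) - rday
    aj = (jmax / 4.0) * (ci - gs) / (ci + 2.0 * gs) - rday
    atpu = 3.0 * tpu - (rday if tpu_net else 0.0)
    return np.minimum(np.minimum(ac, aj), atpu)
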
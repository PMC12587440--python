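"""Solid-liquid equilibrium of a crystalline drug in an amorphous polymer.

The solubility condition equates the chemical potential of the pure
crystalline API with that of the API dissolved in the polymer melt::

    x_API = (1 / gamma_API) * exp(K(T))

where the fusion bracket ``K(T)`` collects the enthalpy-of-fusion term and
the heat-capacity-difference integrals between the melting onset ``Tm`` and
the temperature of interest, and ``gamma_API`` comes from PC-SAFT
(:mod:`pcsaftsle.eos`).  ``delta_fus_Cp`` may be constant or linear in T,
``Cp(T) = a + b*T``; both integrals then have closed forms.

All activity-coefficient evaluations are performed at ambient pressure
(condensed-phase properties are insensitive to pressure over the relevant
range).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .eos import (
    STANDARD_PRESSURE,
    BinarySystem,
    DomainError,
    solve_density,
    _pack_system,
    _pure_lnphi_cached,
    _rho_from_eta,
    _thermo,
)

__all__ = [
    "GAS_CONSTANT",
    "MeltingProperties",
    "SolubilityPoint",
    "SolubilitySolverError",
    "fusion_exponent",
    "ideal_solubility",
    "solve_solubility",
    "solubility_curve",
    "mole_weight_convert",
]

GAS_CONSTANT = 8.31446261815324  # J/(mol K)


class SolubilitySolverError(RuntimeError):
    """Fixed-point iteration for the solubility condition failed."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class MeltingProperties:
    """Fusion thermodynamics of a pure API.

    ``Tm_onset`` in K, ``dfusH`` in J/mol, and a (possibly T-dependent)
    heat-capacity difference ``delta_fus_Cp(T) = dfusCp_a + dfusCp_b * T``
    in J/(mol K) with T in kelvin.
    """

    Tm_onset: float
    dfusH: float
    dfusCp_a: float = 0.0
    dfusCp_b: float = 0.0

    def __post_init__(self) -> None:
        if self.Tm_onset <= 0:
            raise DomainError("Tm_onset must be positive")
        if self.dfusH <= 0:
            raise DomainError("enthalpy of fusion must be positive")

    def dfusCp(self, T: float) -> float:
        return self.dfusCp_a + self.dfusCp_b * T


@dataclass(frozen=True)
class SolubilityPoint:
    """One point of a solubility curve (mole and weight fraction of API)."""

    T: float
    x_API: float
    w_API: float
    gamma_API: float = float("nan")
    converged: bool = True


def fusion_exponent(T: float, props: MeltingProperties) -> float:
    """The full dimensionless exponent of the solubility condition.

    ``-dfusH/RT (1 - T/Tm) - (1/RT) int_Tm^T Cp dT + (1/R) int_Tm^T Cp/T dT``
    with both integrals in closed form for linear ``Cp(T) = a + b T``::

        int Cp dT   = a (T - Tm) + b/2 (T^2 - Tm^2)
        int Cp/T dT = a ln(T/Tm) + b (T - Tm)
    """
    if T <= 0:
        raise DomainError("temperature must be positive")
    Tm = props.Tm_onset
    a, b = props.dfusCp_a, props.dfusCp_b
    R = GAS_CONSTANT
    term_h = -props.dfusH / (R * T) * (1.0 - T / Tm)
    int_cp = a * (T - Tm) + 0.5 * b * (T * T - Tm * Tm)
    int_cp_over_t = a * math.log(T / Tm) + b * (T - Tm)
    return term_h - int_cp / (R * T) + int_cp_over_t / R


def ideal_solubility(T: float, props: MeltingProperties) -> float:
    """Mole-fraction solubility with gamma = 1 (athermal reference)."""
    if T > props.Tm_onset:
        raise DomainError(
            f"T={T} K above melting onset {props.Tm_onset} K: crystal not stable"
        )
    return math.exp(fusion_exponent(T, props))


def mole_weight_convert(
    value: float, Mw_API: float, Mw_polymer: float, direction: str = "x_to_w"
) -> float:
    """Convert API mole fraction to weight fraction (or back).

    ``w = x M_API / (x M_API + (1 - x) M_poly)``; the inverse is exact.
    """
    if Mw_API <= 0 or Mw_polymer <= 0:
        raise DomainError("molar masses must be positive")
    if not 0.0 < value <= 1.0:
        raise DomainError("fraction must lie in (0, 1]")
    if direction == "x_to_w":
        x = value
        return x * Mw_API / (x * Mw_API + (1.0 - x) * Mw_polymer)
    if direction == "w_to_x":
        w = value
        return (w / Mw_API) / (w / Mw_API + (1.0 - w) / Mw_polymer)
    raise DomainError(f"unknown direction {direction!r}")


def solve_solubility(
    T: float,
    system: BinarySystem,
    props: MeltingProperties,
    P: float = STANDARD_PRESSURE,
    x0: float | None = None,
    damping: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> SolubilityPoint:
    """Solve ``x gamma(x) = exp(K(T))`` by damped successive substitution.

    Starts from the ideal solubility (or ``x0``), damps the update by
    ``damping`` and iterates until the step is below ``tol`` *and* the
    solubility-condition residual ``|x gamma - exp(K)|`` is below 1e-9.
    """
    if T >= props.Tm_onset:
        raise DomainError(
            f"T={T} K at or above melting onset {props.Tm_onset} K"
        )
    K = math.exp(fusion_exponent(T, props))
    x = x0 if x0 is not None else min(ideal_solubility(T, props), 1.0 - 1e-12)
    x = min(max(x, 1e-12), 1.0 - 1e-12)
    trace: list[float] = []
    state = {"eta": None}
    mix = _pack_system(system)
    ln_pure = _pure_lnphi_cached(T, P, system, 0)

    def gamma_at(xval: float) -> float:
        xv = np.array([xval, 1.0 - xval])
        state["eta"] = solve_density(T, P, xv, system, "liquid", eta_guess=state["eta"])
        rho = _rho_from_eta(T, state["eta"], xv, mix)
        th = _thermo(T, rho, xv, mix)
        return math.exp(float(th["mu"][0]) - math.log(th["Z"]) - ln_pure)

    gamma = 1.0
    for _ in range(max_iter):
        gamma = gamma_at(x)
        target = K / gamma
        new = x + damping * (target - x)
        new = min(max(new, 1e-12), 1.0 - 1e-12)
        trace.append(new)
        step = abs(new - x)
        x = new
        if step < tol and abs(x * gamma - K) < 1e-9:
            w = mole_weight_convert(x, system.api.Mw, system.polymer.Mw)
            return SolubilityPoint(T=T, x_API=x, w_API=w, gamma_API=gamma)
        if len(trace) >= 25 and step > 0.05:
            break  # oscillating, not contracting: go to the bracketed solve

    # Successive substitution oscillates when gamma varies steeply with x
    # (strong cross-association, gamma << 1).  Fall back to a bracketed root
    # solve of h(x) = ln(x gamma(x) / K), scanning down from the drug-rich
    # side: h(1) = -ln K > 0 below Tm and h -> -inf as x -> 0, so the
    # topmost sign change brackets the solubility root that connects
    # continuously to x = 1 at Tm.
    def h(xval: float) -> float:
        return math.log(xval) + math.log(gamma_at(xval)) - math.log(K)

    from scipy.optimize import brentq

    scan = np.concatenate(
        [
            np.array([1.0 - 1e-10, 0.999, 0.99]),
            np.arange(0.97, 0.02, -0.03),
            np.array([0.01, 1e-3, 1e-4, 1e-5, 1e-6]),
        ]
    )
    prev_x = prev_h = None
    for xs in scan:
        try:
            hv = h(float(xs))
        except (DomainError, RuntimeError):
            prev_x = prev_h = None
            continue
        if prev_h is not None and prev_h * hv < 0:
            x = float(brentq(h, xs, prev_x, xtol=1e-15, rtol=8.882e-16))
            gamma = gamma_at(x)
            trace.append(x)
            if abs(x * gamma - K) < 1e-9:
                w = mole_weight_convert(x, system.api.Mw, system.polymer.Mw)
                return SolubilityPoint(T=T, x_API=x, w_API=w, gamma_API=gamma)
            break
        prev_x, prev_h = float(xs), hv
    raise SolubilitySolverError(
        f"solubility condition not solvable at T={T} K "
        f"(last x={x:.6g}, residual={abs(x * gamma - K):.3g})",
        trace,
    )


def solubility_curve(
    T_grid,
    system: BinarySystem,
    props: MeltingProperties,
    P: float = STANDARD_PRESSURE,
) -> list[SolubilityPoint]:
    """Pointwise solubility along ``T_grid``; failed points are flagged.

    Points are solved in ascending T with warm starts; a failed point is
    returned with ``converged=False`` and NaN fractions rather than dropped.
    """
    order = np.argsort(np.asarray(T_grid, dtype=float))
    points: dict[int, SolubilityPoint] = {}
    x_prev: float | None = None
    for idx in order:
        T = float(np.asarray(T_grid, dtype=float)[idx])
        try:
            pt = solve_solubility(T, system, props, P=P, x0=x_prev)
            x_prev = pt.x_API
        except (DomainError, SolubilitySolverError, RuntimeError):
            pt = SolubilityPoint(
                T=T, x_API=float("nan"), w_API=float("nan"), converged=False
            )
        points[int(idx)] = pt
    return [points[i] for i in range(len(points))]
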
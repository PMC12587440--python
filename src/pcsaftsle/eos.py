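"""Perturbed-chain SAFT (PC-SAFT) thermodynamics for binary drug-polymer mixtures.

Implements the residual Helmholtz energy of the Gross-Sadowski perturbed-chain
model as the sum of a hard-sphere-chain reference, a second-order perturbation
dispersion term, and a Wertheim-type association term, together with the
pressure, density, fugacity-coefficient and activity-coefficient machinery
needed for solid-liquid equilibrium work.

Conventions
-----------
* Segment diameters ``sigma`` in angstrom, energies as ``u/kB`` in kelvin.
* Number densities internally in molecules per cubic angstrom; pressures in Pa.
* Chemical potentials are residual quantities at fixed (T, V), reduced by kT,
  obtained analytically from the mole-number derivatives of the total residual
  Helmholtz energy; ``ln phi_i = mu_i^res/kT - ln Z`` and the compressibility
  factor follows from the Euler identity ``Z = 1 + sum_i x_i mu_i - a_res``.
* All mixture quantities use Lorentz (sigma) / Berthelot (u, with ``1 - k_ij``)
  combining rules; cross-association uses the Wolbach-Sandler rules, which is
  what gives polymers with zero self-association energy their induced
  association with hydrogen-bonding drugs.
* Association sites are represented as two site *types* per molecule (donor,
  acceptor) with integer multiplicities; donors bind only acceptors.  Site
  fractions are solved by damped successive substitution (damping 0.5,
  residual < 1e-12, at most 500 sweeps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numba import njit
from scipy.optimize import brentq

__all__ = [
    "KB",
    "N_AV",
    "STANDARD_PRESSURE",
    "AssociationScheme",
    "Component",
    "BinarySystem",
    "MixtureState",
    "ModelConstants",
    "MODEL_CONSTANTS",
    "DomainError",
    "DensitySolverError",
    "AssociationSolverError",
    "hard_chain_helmholtz",
    "dispersion_helmholtz",
    "association_helmholtz",
    "residual_helmholtz",
    "pressure_and_Z",
    "solve_density",
    "fugacity_coefficients",
    "activity_coefficient",
]

KB = 1.380649e-23  # J/K
N_AV = 6.02214076e23  # 1/mol
STANDARD_PRESSURE = 1.01325e5  # Pa; all SLE work is done at ambient pressure

#: maximum physically meaningful packing fraction (close packing of spheres)
ETA_CLOSE_PACK = 0.7405
_ETA_MIN = 1e-12

PI = math.pi


class DomainError(ValueError):
    """Input outside the physically valid domain."""


class DensitySolverError(RuntimeError):
    """No density root (or no converged root) for the requested state."""


class AssociationSolverError(RuntimeError):
    """Site-fraction iteration failed to converge."""


# ---------------------------------------------------------------------------
# universal dispersion constants
# ---------------------------------------------------------------------------

# Columns: a_0i, a_1i, a_2i (resp. b_*) of the chain-length dependent
# coefficients of the two perturbation integrals I1 and I2.
_A_COEF = np.array(
    [
        [0.9105631445, -0.3084016918, -0.0906148351],
        [0.6361281449, 0.1860531159, 0.4527842806],
        [2.6861347891, -2.5030047259, 0.5962700728],
        [-26.547362491, 21.419793629, -1.7241829131],
        [97.759208784, -65.255885330, -4.1302112531],
        [-159.59154087, 83.318680481, 13.776631870],
        [91.297774084, -33.746922930, -8.6728470368],
    ]
)
_B_COEF = np.array(
    [
        [0.7240946941, -0.5755498075, 0.0976883116],
        [2.2382791861, 0.6995095521, -0.2557574982],
        [-4.0025849485, 3.8925673390, -9.1558561530],
        [-21.003576815, -17.215471648, 20.642075974],
        [26.855641363, 192.67226447, -38.804430052],
        [206.55133841, -161.82646165, 93.626774077],
        [-355.60235612, -165.20769346, -29.666905585],
    ]
)
_A_COEF.setflags(write=False)
_B_COEF.setflags(write=False)


@dataclass(frozen=True)
class ModelConstants:
    """The two 7x3 arrays of universal dispersion coefficients."""

    a: np.ndarray = field(default_factory=lambda: _A_COEF)
    b: np.ndarray = field(default_factory=lambda: _B_COEF)


MODEL_CONSTANTS = ModelConstants()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationScheme:
    """Hydrogen-bonding description of one substance.

    ``n_donor`` electron-donor sites and ``n_acceptor`` electron-acceptor
    sites (site *types* with integer multiplicities; donors bind only
    acceptors), association energy ``eps_assoc_kB`` in kelvin and
    dimensionless association volume ``kappa_assoc``.
    """

    n_donor: int = 0
    n_acceptor: int = 0
    eps_assoc_kB: float = 0.0
    kappa_assoc: float = 0.0

    def __post_init__(self) -> None:
        if self.n_donor < 0 or self.n_acceptor < 0:
            raise DomainError("site counts must be non-negative")
        if self.eps_assoc_kB < 0:
            raise DomainError("association energy must be non-negative")
        if not 0.0 <= self.kappa_assoc < 1.0:
            raise DomainError("association volume must lie in [0, 1)")


@dataclass(frozen=True)
class Component:
    """One substance's PC-SAFT parameters.

    Uses the mass-normalized segment number ``m_over_Mw`` (mol/g) so polymers
    of different chain length stay on a common parameter scale; the segment
    number itself is ``m = m_over_Mw * Mw``.
    """

    name: str
    Mw: float  # g/mol
    m_over_Mw: float  # mol/g
    sigma: float  # angstrom
    u_kB: float  # K
    assoc: AssociationScheme = field(default_factory=AssociationScheme)

    def __post_init__(self) -> None:
        if self.Mw <= 0:
            raise DomainError(f"{self.name}: Mw must be positive")
        if self.m_over_Mw <= 0:
            raise DomainError(f"{self.name}: m/Mw must be positive")
        if self.sigma <= 0:
            raise DomainError(f"{self.name}: sigma must be positive")
        if self.u_kB < 0:
            raise DomainError(f"{self.name}: u/kB must be non-negative")

    @property
    def m(self) -> float:
        """Segment number m = (m/Mw) * Mw."""
        return self.m_over_Mw * self.Mw


@dataclass(frozen=True)
class BinarySystem:
    """An API-polymer pair with one binary interaction parameter ``k_ij``.

    ``k_ij`` corrects the cross dispersion energy,
    ``u_ij = sqrt(u_i u_j) (1 - k_ij)``; combining rules are symmetric.
    """

    api: Component
    polymer: Component
    k_ij: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.k_ij):
            raise DomainError("k_ij must be finite")

    @property
    def components(self) -> tuple[Component, Component]:
        return (self.api, self.polymer)


@dataclass(frozen=True)
class MixtureState:
    """Temperature, composition and packing fraction of one mixture state."""

    T: float  # K
    x: tuple[float, ...]  # mole fractions
    eta: float  # packing fraction

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise DomainError("temperature must be positive")
        x = np.asarray(self.x, dtype=float)
        if np.any(x < 0) or abs(float(x.sum()) - 1.0) > 1e-12:
            raise DomainError("mole fractions must be non-negative and sum to 1")
        if not _ETA_MIN < self.eta < 0.74:
            raise DomainError("packing fraction must lie in (0, 0.74)")
        object.__setattr__(self, "x", tuple(float(v) for v in x))


# ---------------------------------------------------------------------------
# packed parameter view (fast numeric kernel input)
# ---------------------------------------------------------------------------


class _Mix:
    """Flat numpy view of a component list plus a k_ij matrix."""

    __slots__ = ("m", "sigma", "u", "eps", "kappa", "nd", "na", "Mw", "kij", "n")

    def __init__(self, comps: tuple[Component, ...], kij_matrix: np.ndarray):
        self.n = len(comps)
        self.m = np.array([c.m for c in comps])
        self.sigma = np.array([c.sigma for c in comps])
        self.u = np.array([c.u_kB for c in comps])
        self.eps = np.array([c.assoc.eps_assoc_kB for c in comps])
        self.kappa = np.array([c.assoc.kappa_assoc for c in comps])
        self.nd = np.array([float(c.assoc.n_donor) for c in comps])
        self.na = np.array([float(c.assoc.n_acceptor) for c in comps])
        self.Mw = np.array([c.Mw for c in comps])
        self.kij = np.asarray(kij_matrix, dtype=float)


@lru_cache(maxsize=512)
def _pack_system(system: BinarySystem) -> _Mix:
    k = system.k_ij
    return _Mix(system.components, np.array([[0.0, k], [k, 0.0]]))


def _pack_components(comps: tuple[Component, ...]) -> _Mix:
    n = len(comps)
    return _Mix(tuple(comps), np.zeros((n, n)))


# ---------------------------------------------------------------------------
# numeric kernel (numba-compiled)
# ---------------------------------------------------------------------------

_STATUS_OK = 0
_STATUS_ETA = 1  # packing fraction at/beyond close packing
_STATUS_ASSOC = 2  # site fractions not converged


@njit(cache=True)
def _kernel(T, rho, x, m, sigma, u, eps, kappa, nd, na, kij, acoef, bcoef):
    """All residual thermodynamics at (T, rho, x); see module docstring.

    Returns (status, a_hc, a_disp, a_assoc, mu, Z, XD, XA).
    """
    n = x.shape[0]
    mu = np.zeros(n)
    XD = np.ones(n)
    XA = np.ones(n)

    # temperature-dependent segment diameters
    d = np.empty(n)
    for i in range(n):
        d[i] = sigma[i] * (1.0 - 0.12 * math.exp(-3.0 * u[i] / T))

    # packing fractions zeta_0..zeta_3
    z0 = 0.0
    z1 = 0.0
    z2 = 0.0
    z3 = 0.0
    for i in range(n):
        c = (math.pi / 6.0) * rho * x[i] * m[i]
        z0 += c
        z1 += c * d[i]
        z2 += c * d[i] * d[i]
        z3 += c * d[i] * d[i] * d[i]
    if z3 >= 0.7405:
        return _STATUS_ETA, 0.0, 0.0, 0.0, mu, 0.0, XD, XA
    one = 1.0 - z3
    log1 = math.log(one)

    # --- hard-sphere reference: Phi = (pi/6V) A_hs/kT ---------------------
    phi = 3.0 * z1 * z2 / one + z2**3 / (z3 * one**2) + (z2**3 / z3**2 - z0) * log1
    dphi0 = -log1
    dphi1 = 3.0 * z2 / one
    dphi2 = 3.0 * z1 / one + 3.0 * z2**2 / (z3 * one**2) + 3.0 * z2**2 / z3**2 * log1
    dphi3 = (
        3.0 * z1 * z2 / one**2
        + z2**3 * (-1.0 / (z3**2 * one**2) + 2.0 / (z3 * one**3))
        - 2.0 * z2**3 / z3**3 * log1
        - (z2**3 / z3**2 - z0) / one
    )
    a_hs = (6.0 / math.pi) * phi / rho

    # contact values of the hard-sphere radial distribution function
    g = np.empty((n, n))
    dg2 = np.empty((n, n))
    dg3 = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            gam = d[i] * d[j] / (d[i] + d[j])
            g[i, j] = 1.0 / one + gam * 3.0 * z2 / one**2 + gam * gam * 2.0 * z2 * z2 / one**3
            dg2[i, j] = gam * 3.0 / one**2 + gam * gam * 4.0 * z2 / one**3
            dg3[i, j] = (
                1.0 / one**2
                + gam * 6.0 * z2 / one**3
                + gam * gam * 6.0 * z2 * z2 / one**4
            )

    a_chain = 0.0
    for i in range(n):
        a_chain -= x[i] * (m[i] - 1.0) * math.log(g[i, i])
    a_hc = a_hs + a_chain

    # mu: hard sphere + chain.  A_hs/kT = (6V/pi) Phi and
    # d zeta_k/dN_i = (pi/6) m_i d_i^k / V, so the prefactors cancel.
    c2 = np.empty(n)
    c3 = np.empty(n)
    for i in range(n):
        c2[i] = (math.pi / 6.0) * m[i] * d[i] * d[i]
        c3[i] = (math.pi / 6.0) * m[i] * d[i] * d[i] * d[i]
    s_chain2 = 0.0
    s_chain3 = 0.0
    for j in range(n):
        w = rho * x[j] * (m[j] - 1.0) / g[j, j]
        s_chain2 += w * dg2[j, j]
        s_chain3 += w * dg3[j, j]
    for i in range(n):
        mu[i] += m[i] * (dphi0 + dphi1 * d[i] + dphi2 * d[i] * d[i] + dphi3 * d[i] ** 3)
        mu[i] += -(m[i] - 1.0) * math.log(g[i, i]) - c2[i] * s_chain2 - c3[i] * s_chain3

    # --- dispersion -------------------------------------------------------
    mbar = 0.0
    for i in range(n):
        mbar += x[i] * m[i]
    eta = z3
    S1 = 0.0
    S2 = 0.0
    t1 = np.zeros(n)  # sum_j x_j m_j (u_ij/T) sig_ij^3
    t2 = np.zeros(n)
    for i in range(n):
        for j in range(n):
            uij = math.sqrt(u[i] * u[j]) * (1.0 - kij[i, j])
            sij3 = (0.5 * (sigma[i] + sigma[j])) ** 3
            e1 = m[i] * m[j] * (uij / T) * sij3
            e2 = m[i] * m[j] * (uij / T) ** 2 * sij3
            S1 += x[i] * x[j] * e1
            S2 += x[i] * x[j] * e2
            t1[i] += x[j] * e1 / m[i]
            t2[i] += x[j] * e2 / m[i]

    f1 = (mbar - 1.0) / mbar
    f2 = f1 * (mbar - 2.0) / mbar
    I1 = 0.0
    I2 = 0.0
    I1e = 0.0
    I2e = 0.0
    I1m = 0.0
    I2m = 0.0
    dfm1 = 1.0 / (mbar * mbar)
    dfm2 = 3.0 / (mbar * mbar) - 4.0 / (mbar * mbar * mbar)
    ep = 1.0
    for k in range(7):
        ak = acoef[k, 0] + f1 * acoef[k, 1] + f2 * acoef[k, 2]
        bk = bcoef[k, 0] + f1 * bcoef[k, 1] + f2 * bcoef[k, 2]
        I1 += ak * ep
        I2 += bk * ep
        I1m += (acoef[k, 1] * dfm1 + acoef[k, 2] * dfm2) * ep
        I2m += (bcoef[k, 1] * dfm1 + bcoef[k, 2] * dfm2) * ep
        if k >= 1:
            epm1 = ep / eta if eta > 0.0 else 0.0
            I1e += k * ak * epm1
            I2e += k * bk * epm1
        ep *= eta

    h1 = (8.0 * eta - 2.0 * eta * eta) / one**4
    h2 = (20.0 * eta - 27.0 * eta**2 + 12.0 * eta**3 - 2.0 * eta**4) / (
        one * (2.0 - eta)
    ) ** 2
    C0 = 1.0 + mbar * h1 + (1.0 - mbar) * h2
    C1 = 1.0 / C0
    h1e = (8.0 - 4.0 * eta) / one**4 + 4.0 * (8.0 * eta - 2.0 * eta * eta) / one**5
    uu = 20.0 * eta - 27.0 * eta**2 + 12.0 * eta**3 - 2.0 * eta**4
    vv = (2.0 - 3.0 * eta + eta * eta) ** 2
    uup = 20.0 - 54.0 * eta + 36.0 * eta * eta - 8.0 * eta**3
    vvp = 2.0 * (2.0 - 3.0 * eta + eta * eta) * (2.0 * eta - 3.0)
    h2e = (uup * vv - uu * vvp) / (vv * vv)
    C1e = -(C1 * C1) * (mbar * h1e + (1.0 - mbar) * h2e)
    C1m = -(C1 * C1) * (h1 - h2)

    a_disp = -2.0 * math.pi * rho * I1 * S1 - math.pi * rho * mbar * C1 * I2 * S2

    # d eta/dN_i * V = c3_i; d mbar/dN_i * N = m_i - mbar
    for i in range(n):
        dm = m[i] - mbar
        mu[i] += -2.0 * math.pi * rho * (
            2.0 * I1 * m[i] * t1[i] + S1 * (rho * I1e * c3[i] + I1m * dm)
        ) - math.pi * rho * (
            2.0 * mbar * C1 * I2 * m[i] * t2[i]
            + S2
            * (
                (C1 * I2 + mbar * I2 * C1m + mbar * C1 * I2m) * dm
                + rho * mbar * (I2 * C1e + C1 * I2e) * c3[i]
            )
        )

    # --- association ------------------------------------------------------
    # Donor(i)-acceptor(j) strengths: delta_ij = dbase_ij * g_ij with the
    # Wolbach-Sandler cross rules (eps arithmetic; kappa geometric with a
    # sigma-ratio correction).  dbase carries everything but the density
    # dependence, which enters through the contact value g.
    a_assoc = 0.0
    dbase = np.zeros((n, n))
    any_assoc = False
    for i in range(n):
        for j in range(n):
            sij = 0.5 * (sigma[i] + sigma[j])
            epsij = 0.5 * (eps[i] + eps[j])
            kapij = math.sqrt(kappa[i] * kappa[j]) * (math.sqrt(sigma[i] * sigma[j]) / sij) ** 3
            fij = math.expm1(epsij / T)
            dbase[i, j] = sij**3 * kapij * fij
            if dbase[i, j] * g[i, j] != 0.0 and nd[i] * na[j] > 0.0:
                any_assoc = True

    if any_assoc:
        delta = dbase * g
        # damped successive substitution for the site fractions
        lam = 0.5
        ok = False
        for _sweep in range(500):
            resmax = 0.0
            for i in range(n):
                sD = 0.0
                sA = 0.0
                for j in range(n):
                    sD += rho * x[j] * na[j] * XA[j] * delta[i, j]
                    sA += rho * x[j] * nd[j] * XD[j] * delta[j, i]
                newD = 1.0 / (1.0 + sD)
                newA = 1.0 / (1.0 + sA)
                rD = abs(newD - XD[i])
                rA = abs(newA - XA[i])
                if rD > resmax:
                    resmax = rD
                if rA > resmax:
                    resmax = rA
                XD[i] = (1.0 - lam) * XD[i] + lam * newD
                XA[i] = (1.0 - lam) * XA[i] + lam * newA
            if resmax < 1e-12:
                ok = True
                break
        if not ok:
            return _STATUS_ASSOC, 0.0, 0.0, 0.0, mu, 0.0, XD, XA
        # one exact substitution pass so the mass-action equations hold tightly
        for i in range(n):
            sD = 0.0
            for j in range(n):
                sD += rho * x[j] * na[j] * XA[j] * delta[i, j]
            XD[i] = 1.0 / (1.0 + sD)
        for i in range(n):
            sA = 0.0
            for j in range(n):
                sA += rho * x[j] * nd[j] * XD[j] * delta[j, i]
            XA[i] = 1.0 / (1.0 + sA)

        for i in range(n):
            a_assoc += x[i] * (
                nd[i] * (math.log(XD[i]) - 0.5 * XD[i] + 0.5)
                + na[i] * (math.log(XA[i]) - 0.5 * XA[i] + 0.5)
            )
        # mu_assoc,i = nd_i ln XD_i + na_i ln XA_i
        #   - sum_jk rho_j rho_k nd_j na_k XD_j XA_k dbase_jk
        #            (dg2_jk c2_i + dg3_jk c3_i)
        W2 = 0.0
        W3 = 0.0
        for j in range(n):
            for k in range(n):
                wjk = (rho * x[j] * nd[j] * XD[j]) * (rho * x[k] * na[k] * XA[k]) * dbase[j, k]
                W2 += wjk * dg2[j, k]
                W3 += wjk * dg3[j, k]
        for i in range(n):
            mu[i] += nd[i] * math.log(XD[i]) + na[i] * math.log(XA[i]) - (
                W2 * c2[i] + W3 * c3[i]
            )

    a_res = a_hc + a_disp + a_assoc
    xmu = 0.0
    for i in range(n):
        xmu += x[i] * mu[i]
    Z = 1.0 + xmu - a_res
    return _STATUS_OK, a_hc, a_disp, a_assoc, mu, Z, XD, XA


def _thermo(T: float, rho: float, x: np.ndarray, mix: _Mix) -> dict:
    """Python-facing wrapper of the compiled kernel; raises on bad status."""
    status, a_hc, a_disp, a_assoc, mu, Z, XD, XA = _kernel(
        float(T),
        float(rho),
        np.ascontiguousarray(x, dtype=float),
        mix.m,
        mix.sigma,
        mix.u,
        mix.eps,
        mix.kappa,
        mix.nd,
        mix.na,
        mix.kij,
        _A_COEF,
        _B_COEF,
    )
    if status == _STATUS_ETA:
        raise DomainError("packing fraction at or beyond close packing")
    if status == _STATUS_ASSOC:
        raise AssociationSolverError(
            f"site fractions did not converge (T={T} K, rho={rho:.6g} A^-3, "
            f"x={np.asarray(x).tolist()})"
        )
    return {
        "a_hc": a_hc,
        "a_disp": a_disp,
        "a_assoc": a_assoc,
        "a_res": a_hc + a_disp + a_assoc,
        "mu": mu,
        "Z": Z,
        "XD": XD,
        "XA": XA,
    }


def _rho_from_eta(T: float, eta: float, x: np.ndarray, mix: _Mix) -> float:
    d = mix.sigma * (1.0 - 0.12 * np.exp(-3.0 * mix.u / T))
    return 6.0 * eta / (PI * float((np.asarray(x) * mix.m * d**3).sum()))


def _pressure(T: float, eta: float, x: np.ndarray, mix: _Mix) -> tuple[float, dict]:
    rho = _rho_from_eta(T, eta, x, mix)
    th = _thermo(T, rho, x, mix)
    P = th["Z"] * rho * 1e30 * KB * T
    return P, th


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def hard_chain_helmholtz(state: MixtureState, comps: list[Component]) -> float:
    """Hard-sphere-chain contribution a^hc/RT (repulsion + chain connectivity)."""
    mix = _pack_components(tuple(comps))
    x = np.asarray(state.x, dtype=float)
    rho = _rho_from_eta(state.T, state.eta, x, mix)
    return _thermo(state.T, rho, x, mix)["a_hc"]


def dispersion_helmholtz(state: MixtureState, system: BinarySystem) -> float:
    """Second-order perturbation dispersion contribution a^disp/RT."""
    mix = _pack_system(system)
    x = np.asarray(state.x, dtype=float)
    rho = _rho_from_eta(state.T, state.eta, x, mix)
    return _thermo(state.T, rho, x, mix)["a_disp"]


def association_helmholtz(
    state: MixtureState, system: BinarySystem
) -> tuple[float, dict[str, np.ndarray]]:
    """Wertheim association contribution a^assoc/RT plus converged site fractions."""
    mix = _pack_system(system)
    x = np.asarray(state.x, dtype=float)
    rho = _rho_from_eta(state.T, state.eta, x, mix)
    th = _thermo(state.T, rho, x, mix)
    return th["a_assoc"], {"X_donor": th["XD"], "X_acceptor": th["XA"]}


def residual_helmholtz(state: MixtureState, system: BinarySystem) -> float:
    """Total residual Helmholtz energy a^res/RT = a^hc + a^disp + a^assoc."""
    mix = _pack_system(system)
    x = np.asarray(state.x, dtype=float)
    rho = _rho_from_eta(state.T, state.eta, x, mix)
    return _thermo(state.T, rho, x, mix)["a_res"]


def pressure_and_Z(state: MixtureState, system: BinarySystem) -> tuple[float, float]:
    """Pressure (Pa) and compressibility factor Z at the given state."""
    mix = _pack_system(system)
    x = np.asarray(state.x, dtype=float)
    P, th = _pressure(state.T, state.eta, x, mix)
    return P, th["Z"]


_LIQ_GRID = np.concatenate(
    [
        np.arange(0.72, 0.30, -0.02),
        np.array(
            [0.28, 0.24, 0.20, 0.15, 0.10, 0.05, 0.02, 1e-3, 1e-5, 1e-7, 1e-9, _ETA_MIN]
        ),
    ]
)
_VAP_GRID = _LIQ_GRID[::-1]


def solve_density(
    T: float,
    P: float,
    x,
    system: BinarySystem,
    phase_hint: str | None = "liquid",
    eta_guess: float | None = None,
) -> float:
    """Packing fraction eta solving P(eta) = P.

    ``phase_hint='liquid'`` returns the largest (densest) root, ``'vapor'`` the
    smallest; with no hint all roots are located and the one with the lower
    residual-Gibbs criterion is returned.  The returned root satisfies
    ``|P(eta) - P| / P < 1e-9``.
    """
    if P <= 0:
        raise DomainError("pressure must be positive")
    mix = _pack_system(system)
    xv = np.asarray(x, dtype=float)

    def f(eta: float) -> float:
        return _pressure(T, eta, xv, mix)[0] - P

    def _refine(lo: float, hi: float) -> float:
        if lo == hi:
            return lo
        return float(brentq(f, lo, hi, xtol=1e-15, rtol=8.882e-16, maxiter=200))

    # local bracket around a warm-start guess (used heavily by the SLE solver)
    if eta_guess is not None and _ETA_MIN < eta_guess < 0.72:
        h = 0.01
        lo = max(eta_guess - h, _ETA_MIN)
        hi = min(eta_guess + h, 0.72)
        try:
            flo, fhi = f(lo), f(hi)
        except (DomainError, AssociationSolverError):
            flo = fhi = None
        if flo is not None and flo * fhi < 0:
            root = _refine(lo, hi)
            if abs(f(root)) / P < 1e-9:
                return root

    if phase_hint == "liquid":
        grid = _LIQ_GRID
    elif phase_hint == "vapor":
        grid = _VAP_GRID
    elif phase_hint is None:
        grid = _VAP_GRID
    else:
        raise DomainError(f"unknown phase hint {phase_hint!r}")

    brackets = []
    prev = None
    val_prev = None
    for e in grid:
        try:
            v = f(e)
        except (DomainError, AssociationSolverError):
            prev, val_prev = None, None
            continue
        if val_prev is not None and val_prev * v < 0:
            brackets.append((min(prev, e), max(prev, e)))
            if phase_hint in ("liquid", "vapor"):
                break
        prev, val_prev = e, v

    if not brackets:
        raise DensitySolverError(
            f"no density root in ({_ETA_MIN:g}, {ETA_CLOSE_PACK}) at T={T} K, P={P} Pa"
        )
    roots = [_refine(lo, hi) for lo, hi in brackets]
    if phase_hint == "liquid":
        eta = max(roots)
    elif phase_hint == "vapor":
        eta = min(roots)
    else:
        # lower residual-Gibbs branch: g/NkT differs across roots by
        # ln(rho) + a_res + Z
        def gibbs(eta_r: float) -> float:
            rho = _rho_from_eta(T, eta_r, xv, mix)
            th = _thermo(T, rho, xv, mix)
            return math.log(rho) + th["a_res"] + th["Z"]

        eta = min(roots, key=gibbs)
    if abs(f(eta)) / P >= 1e-9:
        raise DensitySolverError(f"density root not converged at T={T} K, P={P} Pa")
    return eta


def fugacity_coefficients(
    T: float,
    P: float,
    x,
    system: BinarySystem,
    phase_hint: str = "liquid",
    eta_guess: float | None = None,
) -> np.ndarray:
    """ln phi_i of every component in the liquid mixture at (T, P, x).

    Computed analytically from the residual chemical potentials,
    ``ln phi_i = mu_i^res(T,V)/kT - ln Z``.
    """
    xv = np.asarray(x, dtype=float)
    eta = solve_density(T, P, xv, system, phase_hint=phase_hint, eta_guess=eta_guess)
    mix = _pack_system(system)
    rho = _rho_from_eta(T, eta, xv, mix)
    th = _thermo(T, rho, xv, mix)
    return th["mu"] - math.log(th["Z"])


def _delta_like_residual(state: MixtureState, system: BinarySystem) -> float:
    """Max mass-action residual of the converged site fractions.

    Recomputes the association strengths and the fixed-point equations in
    plain numpy, independently of the compiled kernel, and returns
    ``max |X - 1/(1 + rho sum ...)|`` — a diagnostic used by the tests.
    """
    mix = _pack_system(system)
    x = np.asarray(state.x, dtype=float)
    rho = _rho_from_eta(state.T, state.eta, x, mix)
    th = _thermo(state.T, rho, x, mix)
    XD, XA = th["XD"], th["XA"]
    T = state.T
    d = mix.sigma * (1.0 - 0.12 * np.exp(-3.0 * mix.u / T))
    zeta2 = PI / 6.0 * rho * float((x * mix.m * d**2).sum())
    zeta3 = PI / 6.0 * rho * float((x * mix.m * d**3).sum())
    one = 1.0 - zeta3
    gam = d[:, None] * d[None, :] / (d[:, None] + d[None, :])
    g = 1.0 / one + gam * 3.0 * zeta2 / one**2 + gam**2 * 2.0 * zeta2**2 / one**3
    sig_ij = 0.5 * (mix.sigma[:, None] + mix.sigma[None, :])
    eps_ij = 0.5 * (mix.eps[:, None] + mix.eps[None, :])
    kap_ij = np.sqrt(mix.kappa[:, None] * mix.kappa[None, :]) * (
        np.sqrt(mix.sigma[:, None] * mix.sigma[None, :]) / sig_ij
    ) ** 3
    delta = sig_ij**3 * kap_ij * np.expm1(eps_ij / T) * g
    res_d = XD - 1.0 / (1.0 + delta @ (rho * x * mix.na * XA))
    res_a = XA - 1.0 / (1.0 + delta.T @ (rho * x * mix.nd * XD))
    return float(max(np.max(np.abs(res_d)), np.max(np.abs(res_a))))


@lru_cache(maxsize=8192)
def _pure_lnphi_cached(T: float, P: float, system: BinarySystem, i: int) -> float:
    x = np.zeros(2)
    x[i] = 1.0
    return float(fugacity_coefficients(T, P, x, system)[i])


def activity_coefficient(
    T: float,
    P: float,
    x,
    system: BinarySystem,
    i: int,
    eta_guess: float | None = None,
) -> float:
    """Activity coefficient gamma_i = phi_i(mixture) / phi_i(pure liquid i)."""
    xv = np.asarray(x, dtype=float)
    if xv[i] == 1.0:
        return 1.0
    ln_mix = fugacity_coefficients(T, P, xv, system, eta_guess=eta_guess)[i]
    ln_pure = _pure_lnphi_cached(T, P, system, i)
    return math.exp(float(ln_mix) - ln_pure)
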
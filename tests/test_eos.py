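"""Equation-of-state checks: closed-form limits, thermodynamic consistency,
and the independent finite-difference oracle for chemical potentials."""

import math

import numpy as np
import pytest

from pcsaftsle.eos import (
    MODEL_CONSTANTS,
    STANDARD_PRESSURE,
    AssociationScheme,
    BinarySystem,
    Component,
    DensitySolverError,
    DomainError,
    MixtureState,
    activity_coefficient,
    association_helmholtz,
    dispersion_helmholtz,
    fugacity_coefficients,
    hard_chain_helmholtz,
    pressure_and_Z,
    residual_helmholtz,
    solve_density,
    _pack_system,
    _rho_from_eta,
    _thermo,
)


def cs_helmholtz(eta: float) -> float:
    return (4 * eta - 3 * eta**2) / (1 - eta) ** 2


def cs_z(eta: float) -> float:
    return (1 + eta + eta**2 - eta**3) / (1 - eta) ** 3


class TestHardSphereLimits:
    @pytest.mark.parametrize("eta", [0.1, 0.3, 0.4, 0.55])
    def test_carnahan_starling_helmholtz(self, hard_sphere, hs_system, eta):
        """m=1, u=0, eps=0 reduces to the Carnahan-Starling fluid."""
        st = MixtureState(T=400.0, x=(1.0, 0.0), eta=eta)
        a = hard_chain_helmholtz(st, list(hs_system.components))
        assert a == pytest.approx(cs_helmholtz(eta), abs=1e-8)
        assert residual_helmholtz(st, hs_system) == pytest.approx(
            cs_helmholtz(eta), abs=1e-8
        )

    @pytest.mark.parametrize("eta", [0.1, 0.3, 0.4, 0.55])
    def test_carnahan_starling_Z(self, hs_system, eta):
        st = MixtureState(T=400.0, x=(1.0, 0.0), eta=eta)
        _, Z = pressure_and_Z(st, hs_system)
        assert Z == pytest.approx(cs_z(eta), abs=1e-8)

    def test_ideal_gas_limit_Z(self, hs_system, fel_pvp):
        for system in (hs_system, fel_pvp):
            st = MixtureState(T=400.0, x=(1.0, 0.0), eta=1e-10)
            _, Z = pressure_and_Z(st, system)
            assert Z == pytest.approx(1.0, abs=1e-6)


class TestIdealGasLimit:
    def test_helmholtz_vanishes(self, components):
        """a_res -> 0 linearly as eta -> 0 for every published fixture pair.

        The prefactor of the linear decay grows with the polymer segment
        number, so the absolute 1e-6 check is applied deep enough into the
        dilute regime for each system (eta scaled by the mean segment
        number), and the linear vanishing itself is asserted for all pairs.
        """
        names = list(components)
        for api, poly in zip(names[:8], (names[8:] * 3)[:8]):
            system = BinarySystem(components[api], components[poly])
            a9 = residual_helmholtz(
                system=system, state=MixtureState(T=420.0, x=(0.5, 0.5), eta=1e-9)
            )
            a10 = residual_helmholtz(
                system=system, state=MixtureState(T=420.0, x=(0.5, 0.5), eta=1e-10)
            )
            assert a9 / a10 == pytest.approx(10.0, rel=2e-2)
            mbar = 0.5 * (system.api.m + system.polymer.m)
            eta = min(1e-10, 1e-10 / mbar)
            if eta > 1e-12:
                st = MixtureState(T=420.0, x=(0.5, 0.5), eta=eta)
                assert abs(residual_helmholtz(st, system)) < 1e-6
            else:
                # state floor reached: scale the eta=1e-10 value down linearly
                assert abs(a10) * (1e-10 / mbar) / 1e-10 < 1e-6

    def test_lnphi_vanishes(self, fel_pvp):
        mix = _pack_system(fel_pvp)
        x = np.array([0.5, 0.5])
        rho = _rho_from_eta(400.0, 1e-12, x, mix)
        th = _thermo(400.0, rho, x, mix)
        assert np.all(np.abs(th["mu"] - math.log(th["Z"])) < 1e-6)


class TestHelmholtzStructure:
    def test_decomposition_identity(self, fel_pvp):
        st = MixtureState(T=400.0, x=(0.4, 0.6), eta=0.45)
        total = residual_helmholtz(st, fel_pvp)
        parts = (
            hard_chain_helmholtz(st, list(fel_pvp.components))
            + dispersion_helmholtz(st, fel_pvp)
            + association_helmholtz(st, fel_pvp)[0]
        )
        assert total == pytest.approx(parts, abs=1e-14)

    def test_identical_components_match_pure(self, twin_system):
        """An equimolar mixture of identical molecules is the pure fluid."""
        mixed = MixtureState(T=380.0, x=(0.5, 0.5), eta=0.42)
        pure = MixtureState(T=380.0, x=(1.0, 0.0), eta=0.42)
        assert residual_helmholtz(mixed, twin_system) == pytest.approx(
            residual_helmholtz(pure, twin_system), rel=1e-12
        )

    def test_zero_eta_limit(self, twin_system):
        st = MixtureState(T=380.0, x=(0.5, 0.5), eta=1e-11)
        assert abs(residual_helmholtz(st, twin_system)) < 1e-6

    def test_kij_symmetry_under_component_swap(self, components):
        fwd = BinarySystem(components["NAP"], components["SOL"], k_ij=0.05)
        rev = BinarySystem(components["SOL"], components["NAP"], k_ij=0.05)
        st_f = MixtureState(T=400.0, x=(0.3, 0.7), eta=0.45)
        st_r = MixtureState(T=400.0, x=(0.7, 0.3), eta=0.45)
        assert residual_helmholtz(st_f, fwd) == pytest.approx(
            residual_helmholtz(st_r, rev), rel=1e-12
        )


class TestDispersion:
    def test_zero_dispersion_energy(self, hs_system):
        st = MixtureState(T=400.0, x=(0.5, 0.5), eta=0.4)
        assert dispersion_helmholtz(st, hs_system) == 0.0

    def test_negative_at_liquid_density(self, fel_pvp):
        st = MixtureState(T=400.0, x=(0.5, 0.5), eta=0.45)
        assert dispersion_helmholtz(st, fel_pvp) < 0.0

    def test_kij_weakens_cross_attraction(self):
        """k_ij = 1 kills the cross term, making a_disp less negative."""
        scheme = AssociationScheme()
        a = Component("a", 200.0, 0.02, 3.5, 250.0, scheme)
        b = Component("b", 200.0, 0.02, 3.5, 250.0, scheme)
        st = MixtureState(T=400.0, x=(0.5, 0.5), eta=0.45)
        off = dispersion_helmholtz(st, BinarySystem(a, b, k_ij=0.0))
        on = dispersion_helmholtz(st, BinarySystem(a, b, k_ij=1.0))
        assert on > off


class TestAssociation:
    def test_no_energy_means_no_association(self, components):
        """eps = 0 everywhere: all site fractions 1 and a_assoc = 0."""
        pzq = components["PZQ"]  # eps = 0
        poly = components["PVP K12"]  # eps = 0
        st = MixtureState(T=400.0, x=(0.5, 0.5), eta=0.45)
        a, X = association_helmholtz(st, BinarySystem(pzq, poly))
        assert a == 0.0
        assert np.all(X["X_donor"] == 1.0)
        assert np.all(X["X_acceptor"] == 1.0)

    def test_symmetric_scheme_equal_site_fractions(self, fel_pvp):
        """With n_donor = n_acceptor on both species, donors mirror acceptors."""
        st = MixtureState(T=400.0, x=(0.5, 0.5), eta=0.45)
        _, X = association_helmholtz(st, fel_pvp)
        assert X["X_donor"] == pytest.approx(X["X_acceptor"], rel=1e-10)

    def test_site_fraction_monotone_in_density(self, components):
        """Pure IND: bonding increases (X falls) with density at fixed T."""
        ind = components["IND"]
        system = BinarySystem(ind, components["PVP K12"])
        xs = []
        for eta in np.linspace(0.2, 0.55, 8):
            st = MixtureState(T=420.0, x=(1.0, 0.0), eta=float(eta))
            _, X = association_helmholtz(st, system)
            xs.append(float(X["X_donor"][0]))
        assert np.all(np.diff(xs) < 0)

    def test_mass_action_fixed_point(self, fel_pvp):
        """The converged site fractions satisfy the mass-action equations."""
        from pcsaftsle.eos import _delta_like_residual

        st = MixtureState(T=400.0, x=(0.4, 0.6), eta=0.45)
        res = _delta_like_residual(st, fel_pvp)
        assert res < 1e-12

    def test_kappa_zero_reproduces_no_association(self, components):
        fel = components["FEL"]
        fel_off = Component(
            "FEL-off", fel.Mw, fel.m_over_Mw, fel.sigma, fel.u_kB,
            AssociationScheme(2, 2, fel.assoc.eps_assoc_kB, 0.0),
        )
        poly = components["PVP K12"]
        poly_off = Component(
            "PVP-off", poly.Mw, poly.m_over_Mw, poly.sigma, poly.u_kB,
            AssociationScheme(22, 22, 0.0, 0.0),
        )
        st = MixtureState(T=400.0, x=(0.5, 0.5), eta=0.45)
        a_off = association_helmholtz(st, BinarySystem(fel_off, poly_off))[0]
        assert a_off == 0.0
        with_assoc = residual_helmholtz(st, BinarySystem(fel, poly))
        without = residual_helmholtz(st, BinarySystem(fel_off, poly_off))
        a_assoc = association_helmholtz(st, BinarySystem(fel, poly))[0]
        assert with_assoc - without == pytest.approx(a_assoc, abs=1e-12)


class TestChemicalPotentialOracle:
    """ln phi from the analytic route vs central finite differences of the
    total residual Helmholtz energy with respect to mole numbers."""

    def mu_fd(self, T, rho, x, mix, h=1e-6):
        V = 1.0 / rho  # volume per total mole number 1

        def F(n):
            ntot = n.sum()
            return ntot * _thermo(T, ntot / V, n / ntot, mix)["a_res"]

        out = np.zeros(2)
        for i in range(2):
            p = x.copy()
            q = x.copy()
            p[i] += h
            q[i] -= h
            out[i] = (F(p) - F(q)) / (2 * h)
        return out

    @pytest.mark.parametrize("pair", ["fel_pvp", "nap_sol", "pzq_pvp"])
    def test_matches_finite_differences(self, pair, request):
        system = request.getfixturevalue(pair)
        mix = _pack_system(system)
        rng = np.random.default_rng(7)
        for _ in range(5):
            T = rng.uniform(330.0, 450.0)
            x1 = rng.uniform(0.05, 0.95)
            x = np.array([x1, 1.0 - x1])
            eta = rng.uniform(0.35, 0.55)
            rho = _rho_from_eta(T, eta, x, mix)
            th = _thermo(T, rho, x, mix)
            fd = self.mu_fd(T, rho, x, mix)
            assert np.all(
                np.abs(th["mu"] - fd) / np.maximum(np.abs(fd), 1e-10) < 1e-6
            )


class TestPressureAndDensity:
    def test_pressure_monotone_on_liquid_branch(self, components):
        """Mechanical stability: P rises with eta on the dense branch."""
        fel = components["FEL"]
        system = BinarySystem(fel, components["PVP K12"])
        ps = [
            pressure_and_Z(MixtureState(T=400.0, x=(1.0, 0.0), eta=float(e)), system)[0]
            for e in np.linspace(0.40, 0.60, 9)
        ]
        assert np.all(np.diff(ps) > 0)

    def test_density_inverts_carnahan_starling(self, hs_system):
        """P chosen so that CS gives eta = 0.3 is inverted to 0.3."""
        eta0 = 0.3
        st = MixtureState(T=400.0, x=(1.0, 0.0), eta=eta0)
        P, _ = pressure_and_Z(st, hs_system)
        eta = solve_density(400.0, P, [1.0, 0.0], hs_system, phase_hint="liquid")
        assert eta == pytest.approx(eta0, abs=1e-8)

    def test_round_trip(self, fel_pvp):
        st = MixtureState(T=400.0, x=(0.5, 0.5), eta=0.45)
        P, _ = pressure_and_Z(st, fel_pvp)
        eta = solve_density(400.0, P, [0.5, 0.5], fel_pvp, phase_hint="liquid")
        assert eta == pytest.approx(0.45, abs=1e-9)

    def test_vapor_branch_ideal_gas_scaling(self, hs_system):
        etas = [
            solve_density(400.0, P, [1.0, 0.0], hs_system, phase_hint="vapor")
            for P in (10.0, 20.0)
        ]
        assert etas[1] / etas[0] == pytest.approx(2.0, rel=1e-3)

    def test_no_root_raises(self, hs_system):
        # a hard-sphere fluid cannot reach arbitrarily high pressure roots
        with pytest.raises((DensitySolverError, DomainError)):
            solve_density(400.0, -5.0, [1.0, 0.0], hs_system)


class TestFugacityAndActivity:
    def test_pure_limit_consistency(self, fel_pvp):
        lnphi = fugacity_coefficients(400.0, STANDARD_PRESSURE, [1.0, 0.0], fel_pvp)
        g = activity_coefficient(400.0, STANDARD_PRESSURE, [1.0, 0.0], fel_pvp, 0)
        assert g == 1.0
        assert np.isfinite(lnphi[0])

    def test_identical_components_equal_lnphi(self, twin_system):
        lnphi = fugacity_coefficients(
            380.0, STANDARD_PRESSURE, [0.3, 0.7], twin_system
        )
        assert lnphi[0] == pytest.approx(lnphi[1], rel=1e-10)
        g = activity_coefficient(380.0, STANDARD_PRESSURE, [0.3, 0.7], twin_system, 0)
        assert g == pytest.approx(1.0, rel=1e-10)

    @pytest.mark.parametrize("pair", ["fel_pvp", "nap_sol"])
    def test_gibbs_duhem(self, pair, request):
        """sum_i x_i d ln phi_i / dx_1 = 0 at fixed (T, P) along the grid."""
        system = request.getfixturevalue(pair)

        def slope(x1: float, h: float) -> np.ndarray:
            lp = fugacity_coefficients(
                400.0, STANDARD_PRESSURE, [x1 + h, 1 - x1 - h], system
            )
            lm = fugacity_coefficients(
                400.0, STANDARD_PRESSURE, [x1 - h, 1 - x1 + h], system
            )
            return (lp - lm) / (2 * h)

        for x1 in np.linspace(0.05, 0.95, 21):
            # Richardson-extrapolated central differences
            d = (4.0 * slope(x1, 1e-4) - slope(x1, 2e-4)) / 3.0
            assert abs(x1 * d[0] + (1 - x1) * d[1]) < 1e-6

    def test_infinite_dilution_activity_finite(self, components):
        system = BinarySystem(components["NAP"], components["PVP K12"])
        g = activity_coefficient(400.0, STANDARD_PRESSURE, [1e-6, 1.0 - 1e-6], system, 0)
        assert math.isfinite(g) and g > 0.0


class TestDomainValidation:
    def test_model_constants_pinned(self):
        a, b = MODEL_CONSTANTS.a, MODEL_CONSTANTS.b
        assert a.shape == b.shape == (7, 3)
        assert float(a.sum()) == pytest.approx(10.469048319, abs=1e-8)
        assert float(b.sum()) == pytest.approx(-255.31641036, abs=1e-7)
        with pytest.raises(ValueError):
            a[0, 0] = 0.0  # read-only

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"T": -1.0, "x": (1.0, 0.0), "eta": 0.4},
            {"T": 300.0, "x": (0.6, 0.6), "eta": 0.4},
            {"T": 300.0, "x": (1.0, 0.0), "eta": 0.8},
            {"T": 300.0, "x": (1.0, 0.0), "eta": 0.0},
        ],
    )
    def test_invalid_state_rejected(self, kwargs):
        with pytest.raises(DomainError):
            MixtureState(**kwargs)

    def test_invalid_component_rejected(self):
        with pytest.raises(DomainError):
            Component("bad", Mw=-1.0, m_over_Mw=0.02, sigma=3.0, u_kB=200.0)
        with pytest.raises(DomainError):
            AssociationScheme(n_donor=-1, n_acceptor=0)
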
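"""Shared fixtures: published parameter tables and small reference systems."""

import pytest
from hypothesis import settings

from pcsaftsle import (
    AssociationScheme,
    BinarySystem,
    Component,
    packaged_components,
    packaged_melting,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def components() -> dict[str, Component]:
    return {c.name: c for c in packaged_components()}


@pytest.fixture(scope="session")
def melting():
    return packaged_melting()


@pytest.fixture(scope="session")
def fel_pvp(components) -> BinarySystem:
    return BinarySystem(components["FEL"], components["PVP K12"])


@pytest.fixture(scope="session")
def nap_sol(components) -> BinarySystem:
    return BinarySystem(components["NAP"], components["SOL"])


@pytest.fixture(scope="session")
def pzq_pvp(components) -> BinarySystem:
    return BinarySystem(components["PZQ"], components["PVP K12"])


@pytest.fixture(scope="session")
def hard_sphere() -> Component:
    """A single-segment sphere with all attractions switched off."""
    return Component("hs", Mw=100.0, m_over_Mw=0.01, sigma=3.5, u_kB=0.0)


@pytest.fixture(scope="session")
def hs_system(hard_sphere) -> BinarySystem:
    other = Component("hs2", Mw=100.0, m_over_Mw=0.01, sigma=3.5, u_kB=0.0)
    return BinarySystem(hard_sphere, other)


@pytest.fixture(scope="session")
def twin_system() -> BinarySystem:
    """Two components with identical parameters (an ideal mixture)."""
    scheme = AssociationScheme(2, 2, 1200.0, 0.02)
    a = Component("twinA", Mw=300.0, m_over_Mw=0.025, sigma=3.6, u_kB=260.0, assoc=scheme)
    b = Component("twinB", Mw=300.0, m_over_Mw=0.025, sigma=3.6, u_kB=260.0, assoc=scheme)
    return BinarySystem(a, b)
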
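"""Shared fixtures: synthetic tables, toy spectrum, fitted models.

Session-scoped because the fits and spectral weightings are reused by
many tests and are deterministic.
"""
from __future__ import annotations

import numpy as np
import pytest

import pcctspr as p
from pcctspr import simulate as sim

MONO_ENERGIES = [40.0, 60.0, 80.0, 100.0]


@pytest.fixture(scope="session")
def exact_table():
    """Power-law table inside both PFM model classes."""
    return sim.make_synthetic_attenuation_table(sim.EXACT_RULES)


@pytest.fixture(scope="session")
def realistic_table():
    """Power-law table with physical per-electron Z-exponents."""
    return sim.make_synthetic_attenuation_table(sim.REALISTIC_RULES)


@pytest.fixture(scope="session")
def toy_spectrum():
    return sim.make_toy_spectrum()


@pytest.fixture(scope="session")
def materials():
    return p.packaged_materials()


@pytest.fixture(scope="session")
def seven_rods(materials):
    names = ("BE-H-10", "BE-N-10", "BE-T-10", "Aluminium", "PMMA", "WD-3010", "Graphite")
    return [materials[n] for n in names]


@pytest.fixture(scope="session")
def two_exact(exact_table):
    return p.fit_two_pfm(exact_table)


@pytest.fixture(scope="session")
def three_exact(exact_table):
    return p.fit_three_pfm(exact_table)


@pytest.fixture(scope="session")
def two_real(realistic_table):
    return p.fit_two_pfm(realistic_table)


@pytest.fixture(scope="session")
def three_real(realistic_table):
    return p.fit_three_pfm(realistic_table)


@pytest.fixture(scope="session")
def mono_two_exact(two_exact):
    return two_exact.at_energies(MONO_ENERGIES)


@pytest.fixture(scope="session")
def mono_three_exact(three_exact):
    return three_exact.at_energies(MONO_ENERGIES)


@pytest.fixture(scope="session")
def weighted_two_real(two_real, toy_spectrum):
    return two_real.weighted(toy_spectrum, p.DEFAULT_WINDOWS)


@pytest.fixture(scope="session")
def weighted_three_real(three_real, toy_spectrum):
    return three_real.weighted(toy_spectrum, p.DEFAULT_WINDOWS)


@pytest.fixture(scope="session")
def mixture_curve():
    return p.fit_ivalue_curve(sim.make_tissue_ivalue_points())


@pytest.fixture(scope="session")
def element_curve():
    from pcctspr.constants import ELEMENTS

    pts = np.array([[rec.Z, rec.I_elem] for rec in ELEMENTS.values()], dtype=float)
    return p.fit_ivalue_curve(pts, source="element-fit")


@pytest.fixture(scope="session")
def beam():
    return p.BeamSpec(290.0)


@pytest.fixture(scope="session")
def water_ref():
    return p.water_reference()
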
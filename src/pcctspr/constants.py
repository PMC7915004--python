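"""Physical constants and the packaged element table (Z = 1–29).

Atomic masses are standard atomic weights to five significant figures.
Element mean excitation energies (I-values, eV) follow ICRU Report 37 /
the Particle Data Group compilation.  Both tables are user-overridable
at the call sites that consume them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

#: Avogadro's number, mol^-1 (CODATA 2018, exact by SI definition)
N_A = 6.02214076e23

#: Electron rest energy, keV
ME_C2_KEV = 510.99895

#: Atomic mass unit rest energy, MeV (for ion kinematics)
M_U_C2_MEV = 931.49410242


@dataclass(frozen=True)
class ElementRecord:
    """One element: atomic number, symbol, mass and mean excitation energy."""

    Z: int
    symbol: str
    A: float  # g/mol
    I_elem: float  # eV

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.Z}")
        if self.A <= 0:
            raise ValueError(f"atomic mass must be > 0, got {self.A}")
        if self.I_elem <= 0:
            raise ValueError(f"I-value must be > 0, got {self.I_elem}")


# (Z, symbol, A [g/mol], I [eV])
_ELEMENT_ROWS = [
    (1, "H", 1.0080, 19.2),
    (2, "He", 4.0026, 41.8),
    (3, "Li", 6.9400, 40.0),
    (4, "Be", 9.0122, 63.7),
    (5, "B", 10.810, 76.0),
    (6, "C", 12.011, 78.0),
    (7, "N", 14.007, 82.0),
    (8, "O", 15.999, 95.0),
    (9, "F", 18.998, 115.0),
    (10, "Ne", 20.180, 137.0),
    (11, "Na", 22.990, 149.0),
    (12, "Mg", 24.305, 156.0),
    (13, "Al", 26.982, 166.0),
    (14, "Si", 28.085, 173.0),
    (15, "P", 30.974, 173.0),
    (16, "S", 32.060, 180.0),
    (17, "Cl", 35.450, 174.0),
    (18, "Ar", 39.948, 188.0),
    (19, "K", 39.098, 190.0),
    (20, "Ca", 40.078, 191.0),
    (21, "Sc", 44.956, 216.0),
    (22, "Ti", 47.867, 233.0),
    (23, "V", 50.942, 245.0),
    (24, "Cr", 51.996, 257.0),
    (25, "Mn", 54.938, 272.0),
    (26, "Fe", 55.845, 286.0),
    (27, "Co", 58.933, 297.0),
    (28, "Ni", 58.693, 311.0),
    (29, "Cu", 63.546, 322.0),
]

#: Element records keyed by atomic number.
ELEMENTS: dict[int, ElementRecord] = {
    z: ElementRecord(z, s, a, i) for z, s, a, i in _ELEMENT_ROWS
}

#: Element records keyed by symbol.
ELEMENTS_BY_SYMBOL: dict[str, ElementRecord] = {
    rec.symbol: rec for rec in ELEMENTS.values()
}


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants entering the mixture rules and the stopping-power formula.

    ``alpha_zeff`` is the exponent of the power-law effective-atomic-number
    mixture rule; values between 2.94 and 4 are in use in the literature
    depending on which attenuation process dominates.  The default 3.3 is
    the value adopted for the theoretical reference calculations here.
    """

    N_A: float = N_A
    me_c2: float = ME_C2_KEV  # keV
    alpha_zeff: float = 3.3

    def __post_init__(self) -> None:
        if not (2.94 <= self.alpha_zeff <= 4.0):
            raise ValueError(
                f"alpha_zeff must lie in [2.94, 4], got {self.alpha_zeff}"
            )


DEFAULT_CONSTANTS = PhysicalConstants()
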
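"""Elemental and mixture bookkeeping.

A :class:`Composition` is a normalised set of elemental mass fractions; a
:class:`Material` adds a name and a mass density.  From these, the module
computes the three "theory" quantities used throughout the package:

* effective atomic number  Z̄ = (Σᵢ ωᵢ Zᵢ^α)^(1/α),
* electron density         ρe = ρ·N_A·Σᵢ ωᵢ Zᵢ/Aᵢ   [cm⁻³],
* mean excitation energy   ln I = Σᵢ ωᵢ(Zᵢ/Aᵢ) ln Iᵢ / Σᵢ ωᵢ(Zᵢ/Aᵢ)
  (Bragg additivity rule)  [eV],

with ωᵢ the mass fractions.  The Z̄ rule is weighted by mass fractions by
default; electron-fraction weighting is selectable because the literature
is split on the convention.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

from .constants import (
    DEFAULT_CONSTANTS,
    ELEMENTS,
    ELEMENTS_BY_SYMBOL,
    ElementRecord,
    PhysicalConstants,
)

__all__ = [
    "Composition",
    "Material",
    "effective_atomic_number",
    "electron_density",
    "bragg_additivity_ivalue",
    "load_materials",
    "save_materials",
    "packaged_materials",
    "WATER",
]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class Composition:
    """Normalised elemental mass fractions.

    ``entries`` maps atomic number -> mass fraction; fractions are
    renormalised to sum to one on construction (idempotent), so callers
    may pass percentages straight from a catalogue table.
    """

    entries: tuple[tuple[int, float], ...]

    @classmethod
    def from_mass_fractions(cls, fractions: Mapping[str | int, float]) -> "Composition":
        if not fractions:
            raise ValueError("composition must contain at least one element")
        items: list[tuple[int, float]] = []
        for key, w in fractions.items():
            if w < 0:
                raise ValueError(f"mass fraction for {key!r} must be >= 0, got {w}")
            if isinstance(key, str):
                try:
                    z = ELEMENTS_BY_SYMBOL[key].Z
                except KeyError as exc:
                    raise KeyError(f"unknown element symbol {key!r}") from exc
            else:
                z = int(key)
                if z not in ELEMENTS:
                    raise KeyError(f"element Z={z} outside packaged table (Z=1..29)")
            items.append((z, float(w)))
        total = sum(w for _, w in items)
        if total <= 0:
            raise ValueError("mass fractions sum to zero")
        items = [(z, w / total) for z, w in items if w > 0]
        items.sort()
        return cls(entries=tuple(items))

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("composition must contain at least one element")
        total = sum(w for _, w in self.entries)
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError(f"mass fractions must sum to 1, got {total}")

    @property
    def Z(self) -> np.ndarray:
        return np.array([z for z, _ in self.entries], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.entries], dtype=float)

    def as_symbol_dict(self) -> dict[str, float]:
        return {ELEMENTS[z].symbol: w for z, w in self.entries}


@dataclass(frozen=True)
class Material:
    """A named mixture with mass density in g/cm³."""

    name: str
    composition: Composition
    rho: float

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError(f"density must be >= 0, got {self.rho}")


def _za_ratio(comp: Composition, masses: Mapping[int, float] | None = None) -> np.ndarray:
    if masses is None:
        a = np.array([ELEMENTS[z].A for z, _ in comp.entries])
    else:
        a = np.array([masses[z] for z, _ in comp.entries])
    return comp.Z / a


def effective_atomic_number(
    comp: Composition,
    alpha: float = DEFAULT_CONSTANTS.alpha_zeff,
    weighting: str = "mass",
) -> float:
    """Power-law effective atomic number (Σ λᵢ Zᵢ^α)^(1/α).

    ``weighting="mass"`` uses the mass fractions λᵢ=ωᵢ directly (the
    convention that reproduces the packaged phantom reference values);
    ``"electron"`` uses normalised electron fractions ωᵢZᵢ/Aᵢ.
    A single-element composition returns its Z exactly.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    z = comp.Z
    if weighting == "mass":
        lam = comp.weights
    elif weighting == "electron":
        lam = comp.weights * _za_ratio(comp)
        lam = lam / lam.sum()
    else:
        raise ValueError(f"weighting must be 'mass' or 'electron', got {weighting!r}")
    if len(z) == 1:
        return float(z[0])
    # evaluate in log space for numerical headroom at large alpha
    return float(np.exp(np.log(np.sum(lam * z**alpha)) / alpha))


def electron_density(
    mat: Material, consts: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Electron density ρ·N_A·Σ ωᵢZᵢ/Aᵢ in electrons/cm³ (0 for ρ=0)."""
    comp = mat.composition
    return float(mat.rho * consts.N_A * np.sum(comp.weights * _za_ratio(comp)))


def bragg_additivity_ivalue(
    comp: Composition,
    ivalues: Mapping[int, float] | None = None,
) -> float:
    """Mixture mean excitation energy (eV) by the Bragg additivity rule.

    Electron-fraction-weighted logarithmic mean of the element I-values;
    a single element returns its own I-value exactly.  ``ivalues`` may
    override the packaged element table per atomic number.
    """
    i_elem = []
    for z, _ in comp.entries:
        if ivalues is not None and z in ivalues:
            i_elem.append(ivalues[z])
        elif z in ELEMENTS:
            i_elem.append(ELEMENTS[z].I_elem)
        else:
            raise KeyError(f"no I-value available for element Z={z}")
    i_elem = np.array(i_elem, dtype=float)
    lam = comp.weights * _za_ratio(comp)
    return float(np.exp(np.sum(lam * np.log(i_elem)) / np.sum(lam)))


# ---------------------------------------------------------------------------
# JSON interchange:  {name, density_g_cm3, mass_fractions: {symbol: fraction}}
# ---------------------------------------------------------------------------

def _material_from_record(rec: Mapping) -> Material:
    comp = Composition.from_mass_fractions(rec["mass_fractions"])
    return Material(name=rec["name"], composition=comp, rho=float(rec["density_g_cm3"]))


def load_materials(path) -> dict[str, Material]:
    """Read a JSON list of material records into a name-keyed dict."""
    with open(path) as fh:
        records = json.load(fh)
    mats = {}
    for rec in records:
        mat = _material_from_record(rec)
        mats[mat.name] = mat
    return mats


def save_materials(mats: Iterable[Material], path) -> None:
    records = [
        {
            "name": m.name,
            "density_g_cm3": m.rho,
            "mass_fractions": m.composition.as_symbol_dict(),
        }
        for m in mats
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def packaged_materials() -> dict[str, Material]:
    """The packaged material set: four biological phantom rods (catalogue
    compositions and densities), aluminium, graphite, PMMA and water."""
    src = resources.files("pcctspr").joinpath("data/materials.json")
    records = json.loads(src.read_text())
    mats = {}
    for rec in records:
        mat = _material_from_record(rec)
        mats[mat.name] = mat
    return mats


def _water() -> Material:
    return Material(
        "Water",
        Composition.from_mass_fractions({"H": 11.19, "O": 88.81}),
        1.000,
    )


#: Reference water material (11.19/88.81 mass %, ρ = 1 g/cm³).
WATER = _water()
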
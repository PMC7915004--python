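"""Stopping-power ratio: I-value parameterisation, Bethe–Bloch ratio,
ion kinematics and water-equivalent-length extraction from Bragg curves.

The mean excitation energy I of a medium is parameterised as a
fourth-order polynomial in effective atomic number, fitted either to
element I-values or to a mixture (tissue-like) point set; the map
pipeline converts each pixel's Z̄ to I through this curve.  The
stopping-power ratio relative to water for an ion of speed β is

    SPR = (ρe,m/ρe,w) · [ln(2 me c² β² / I_m (1−β²)) − β²]
                       / [ln(2 me c² β² / I_w (1−β²)) − β²].

Independently, SPR can be measured as a water-equivalent length: the
shift of the distal-H% depth of a Bragg curve caused by a slab of
physical thickness t_m,  SPR = (R_H,w − R_H,m)/t_m, with H = 80 by
default.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import M_U_C2_MEV, ME_C2_KEV
from .materials import WATER, bragg_additivity_ivalue, electron_density

__all__ = [
    "IvalueCurve",
    "BeamSpec",
    "BraggCurve",
    "fit_ivalue_curve",
    "ivalue_from_zeff",
    "beta_from_energy",
    "spr_bethe",
    "wel_from_bragg",
    "water_reference",
]


@dataclass(frozen=True)
class IvalueCurve:
    """Degree-4 polynomial I(Z̄) in eV with its fit domain.

    ``coeffs`` are in :func:`numpy.polyval` order (highest power first).
    ``source`` records what was fitted: ``"element-fit"`` (element
    I-values vs Z) or ``"mixture-fit"`` (tissue mixtures vs Z̄).
    """

    coeffs: tuple[float, ...]
    domain: tuple[float, float]
    source: str = "mixture-fit"

    def __call__(self, zeff) -> np.ndarray | float:
        z = np.asarray(zeff, dtype=float)
        lo, hi = self.domain
        if np.any(z < lo) or np.any(z > hi):
            warnings.warn(
                f"Z-eff outside I-value fit domain [{lo:.2f}, {hi:.2f}]; extrapolating",
                stacklevel=2,
            )
        out = np.polyval(self.coeffs, z)
        return float(out) if out.ndim == 0 else out


def fit_ivalue_curve(points, source: str = "mixture-fit") -> IvalueCurve:
    """Least-squares quartic through (Z̄, I[eV]) points.

    With exactly five points the quartic interpolates them exactly.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (zeff, I_eV)")
    if pts.shape[0] < 5:
        raise ValueError("need at least 5 points for a fourth-order polynomial")
    coeffs = np.polyfit(pts[:, 0], pts[:, 1], deg=4)
    return IvalueCurve(
        coeffs=tuple(coeffs),
        domain=(float(pts[:, 0].min()), float(pts[:, 0].max())),
        source=source,
    )


def ivalue_from_zeff(curve: IvalueCurve, zeff) -> float | np.ndarray:
    """Evaluate the fitted I(Z̄) curve (warns on extrapolation)."""
    return curve(zeff)


@dataclass(frozen=True)
class BeamSpec:
    """Ion beam: species metadata and kinetic energy per nucleon."""

    T_MeV_u: float
    ion: str = "12C"
    charge: int = 6

    def __post_init__(self) -> None:
        if self.T_MeV_u <= 0:
            raise ValueError("kinetic energy per nucleon must be positive")

    @property
    def beta(self) -> float:
        return beta_from_energy(self.T_MeV_u)


def beta_from_energy(T_per_u: float) -> float:
    """β = v/c from kinetic energy per nucleon (MeV/u).

    Relativistic kinematics with the atomic mass unit rest energy:
    γ = 1 + T/(m_u c²), β = sqrt(1 − γ⁻²).
    """
    if T_per_u <= 0:
        raise ValueError(f"kinetic energy must be positive, got {T_per_u}")
    gamma = 1.0 + T_per_u / M_U_C2_MEV
    return float(np.sqrt(1.0 - gamma**-2))


def spr_bethe(
    rhoe_m: float,
    I_m_eV: float,
    beam: BeamSpec | float,
    water: tuple[float, float],
) -> float:
    """Bethe–Bloch stopping-power ratio of a medium relative to water.

    Parameters
    ----------
    rhoe_m, I_m_eV:
        Electron density (cm⁻³) and mean excitation energy (eV) of the
        medium.
    beam:
        :class:`BeamSpec` or β directly.
    water:
        Tuple (ρe_w [cm⁻³], I_w [eV]).
    """
    beta = beam.beta if isinstance(beam, BeamSpec) else float(beam)
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    rhoe_w, I_w_eV = water
    if rhoe_m <= 0 or rhoe_w <= 0 or I_m_eV <= 0 or I_w_eV <= 0:
        raise ValueError("densities and I-values must be positive")
    me_c2_eV = ME_C2_KEV * 1e3
    b2 = beta * beta
    arg_m = 2.0 * me_c2_eV * b2 / (I_m_eV * (1.0 - b2))
    arg_w = 2.0 * me_c2_eV * b2 / (I_w_eV * (1.0 - b2))
    if np.any(np.asarray(arg_m) <= 0) or np.any(np.asarray(arg_w) <= 0):
        raise ValueError("logarithm argument non-positive in Bethe formula")
    num = np.log(arg_m) - b2
    den = np.log(arg_w) - b2
    return (rhoe_m / rhoe_w) * num / den


def water_reference(I_w_eV: float | None = None) -> tuple[float, float]:
    """(ρe_w, I_w) for water.

    ρe_w comes from the packaged water composition (≈3.343e23 cm⁻³).
    By default I_w is computed by Bragg additivity from the packaged
    element I-values (≈69 eV), keeping the SPR chain internally
    consistent; pass an explicit value (e.g. 75 or 78) to override.
    """
    rhoe_w = electron_density(WATER)
    if I_w_eV is None:
        I_w_eV = bragg_additivity_ivalue(WATER.composition)
    return rhoe_w, float(I_w_eV)


@dataclass(frozen=True)
class BraggCurve:
    """Depth–ionisation profile with an interior peak."""

    depth_mm: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "depth_mm", np.asarray(self.depth_mm, dtype=float))
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        if self.depth_mm.size < 10:
            raise ValueError("Bragg curve needs at least 10 samples")
        if np.any(np.diff(self.depth_mm) <= 0):
            raise ValueError("depths must be strictly ascending")
        ipk = int(np.argmax(self.signal))
        if ipk == 0 or ipk == self.signal.size - 1:
            raise ValueError("Bragg peak must be interior to the depth range")

    def distal_depth(self, H: float = 80.0) -> float:
        """Depth beyond the peak where the signal first falls to H% of
        the peak, by linear interpolation between bracketing samples."""
        if not 0 < H < 100:
            raise ValueError("H must be a percentage in (0, 100)")
        ipk = int(np.argmax(self.signal))
        level = self.signal[ipk] * H / 100.0
        s = self.signal[ipk:]
        d = self.depth_mm[ipk:]
        below = np.where(s < level)[0]
        if below.size == 0:
            raise ValueError(f"curve never falls below {H}% of peak distally")
        j = below[0]
        # linear interpolation between samples j-1 (>= level) and j (< level)
        frac = (s[j - 1] - level) / (s[j - 1] - s[j])
        return float(d[j - 1] + frac * (d[j] - d[j - 1]))


def wel_from_bragg(
    reference: BraggCurve,
    with_slab: BraggCurve,
    t_m: float,
    H: float = 80.0,
) -> float:
    """Water-equivalent length per slab thickness: (R_H,w − R_H,m)/t_m.

    ``reference`` is the water-only curve; ``with_slab`` the curve with a
    slab of physical thickness ``t_m`` (mm) inserted, which pulls the
    peak shallower by the slab's water-equivalent thickness.
    """
    if t_m <= 0:
        raise ValueError(f"slab thickness must be positive, got {t_m}")
    r_w = reference.distal_depth(H)
    r_m = with_slab.distal_depth(H)
    return (r_w - r_m) / t_m
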
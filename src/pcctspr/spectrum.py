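"""X-ray spectrum handling: spline interpolation of measured fluence,
energy windows, per-window normalised spectral weights and mean energies.

A counting detector with four thresholds yields four energy windows
(default 40–60, 60–80, 80–100, 100–120 keV).  Within a window the
normalised weight  ω(E) = Φ(E)/∫Φ dE  turns any energy-dependent quantity
into its fluence-weighted window average; the mean window energy is
⟨E⟩ = ∫E·Φ dE / ∫Φ dE.  All integrals use a shared 0.1 keV resampling
step and the composite trapezoid rule.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "SpectrumModel",
    "EnergyWindow",
    "WindowWeights",
    "DEFAULT_WINDOWS",
    "interpolate_spectrum",
    "window_weights",
    "mean_energy",
    "RESAMPLE_STEP_KEV",
]

#: Shared resampling step for all spectral integrals, keV.
RESAMPLE_STEP_KEV = 0.1


@dataclass(frozen=True)
class EnergyWindow:
    """Half-open-by-convention energy bin [E_lo, E_hi] of threshold k."""

    k: int
    E_lo: float
    E_hi: float

    def __post_init__(self) -> None:
        if not self.E_lo < self.E_hi:
            raise ValueError(f"window {self.k}: E_lo must be < E_hi")

    def grid(self, step: float = RESAMPLE_STEP_KEV) -> np.ndarray:
        n = int(round((self.E_hi - self.E_lo) / step))
        return np.linspace(self.E_lo, self.E_hi, n + 1)


#: The four default counting windows, keV.
DEFAULT_WINDOWS: tuple[EnergyWindow, ...] = (
    EnergyWindow(1, 40.0, 60.0),
    EnergyWindow(2, 60.0, 80.0),
    EnergyWindow(3, 80.0, 100.0),
    EnergyWindow(4, 100.0, 120.0),
)


def validate_windows(windows: Sequence[EnergyWindow]) -> None:
    """Windows must be non-overlapping and contiguous in ascending order."""
    for a, b in zip(windows, windows[1:]):
        if not np.isclose(a.E_hi, b.E_lo):
            raise ValueError(
                f"windows {a.k} and {b.k} are not contiguous: "
                f"{a.E_hi} != {b.E_lo}"
            )


class SpectrumModel:
    """Fluence Φ(E) as a natural cubic spline through measured points.

    Cubic splines can overshoot below zero near steep spectral edges;
    evaluations are clipped at zero since fluence is a physical density.
    """

    def __init__(self, energies: np.ndarray, fluence: np.ndarray):
        energies = np.asarray(energies, dtype=float)
        fluence = np.asarray(fluence, dtype=float)
        if energies.ndim != 1 or energies.size < 4:
            raise ValueError("spectrum needs at least 4 points")
        if np.any(np.diff(energies) <= 0):
            raise ValueError("spectrum energies must be strictly ascending")
        if np.any(fluence < 0):
            raise ValueError("fluence values must be non-negative")
        self.energies = energies
        self.fluence = fluence
        self._spline = CubicSpline(energies, fluence, bc_type="natural")

    @property
    def E_min(self) -> float:
        return float(self.energies[0])

    @property
    def E_max(self) -> float:
        return float(self.energies[-1])

    def __call__(self, E) -> np.ndarray:
        return np.clip(self._spline(np.asarray(E, dtype=float)), 0.0, None)

    def check_covers(self, window: EnergyWindow) -> None:
        if window.E_lo < self.E_min - 1e-9 or window.E_hi > self.E_max + 1e-9:
            raise ValueError(
                f"window {window.k} [{window.E_lo}, {window.E_hi}] keV outside "
                f"spectrum range [{self.E_min}, {self.E_max}] keV"
            )


@dataclass(frozen=True)
class WindowWeights:
    """Normalised spectral weight ω(E) on a window grid (∫ω dE = 1)."""

    window: EnergyWindow
    grid: np.ndarray
    omega: np.ndarray

    def integral(self) -> float:
        return float(np.trapezoid(self.omega, self.grid))


def interpolate_spectrum(points) -> SpectrumModel:
    """Build a :class:`SpectrumModel` from (keV, fluence) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (keV, fluence)")
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 spectrum points for spline interpolation")
    return SpectrumModel(pts[:, 0], pts[:, 1])


def window_weights(
    spec: SpectrumModel,
    window: EnergyWindow,
    step: float = RESAMPLE_STEP_KEV,
) -> WindowWeights:
    """Normalised spectral weighting function of one window."""
    spec.check_covers(window)
    grid = window.grid(step)
    phi = spec(grid)
    total = np.trapezoid(phi, grid)
    if total <= 0:
        raise ValueError(f"window {window.k} has zero total fluence")
    return WindowWeights(window=window, grid=grid, omega=phi / total)


def mean_energy(
    spec: SpectrumModel,
    window: EnergyWindow,
    step: float = RESAMPLE_STEP_KEV,
) -> float:
    """Fluence-weighted mean energy ⟨E⟩ of one window, keV."""
    w = window_weights(spec, window, step)
    return float(np.trapezoid(w.grid * w.omega, w.grid))
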
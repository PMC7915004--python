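"""Attenuation-data layer.

An :class:`AttenuationTable` holds per-element, per-energy photon cross
sections *per electron* (cm²/electron) split into three channels —
photoelectric, incoherent (Compton) and coherent (Rayleigh) scattering —
on a rectangular (E, Z) grid covering 30–150 keV and Z = 1..29.  The
linear attenuation coefficient of a mixture follows from the elemental
sum

    μ(E) = ρ·N_A·Σᵢ ωᵢ (Zᵢ/Aᵢ) · σ(E, Zᵢ),        σ = σ_pe + σ_incoh + σ_coh,

and a polychromatic window attenuation is the fluence-weighted mean

    ⟨μ⟩k = ∫ μ(E) Φ(E) dE / ∫ Φ(E) dE

over the window.  Off-node energies are evaluated by piecewise-linear
interpolation of log σ versus log E, which is the standard scheme for
smooth (edge-free) cross sections in this range.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, ELEMENTS
from .materials import Material
from .spectrum import RESAMPLE_STEP_KEV, EnergyWindow, SpectrumModel, window_weights

__all__ = [
    "AttenuationTable",
    "WindowAttenuation",
    "load_attenuation_table",
    "mu_over_rhoe",
    "mixture_mu",
    "spectrum_weighted_mu",
    "CHANNELS",
]

CHANNELS = ("pe", "incoh", "coh")
_CSV_COLUMNS = ["Z", "E_keV", "sigma_pe", "sigma_incoh", "sigma_coh"]


@dataclass(frozen=True)
class WindowAttenuation:
    """One window's attenuation value (cm⁻¹, or cm²/electron if per-electron)."""

    k: int
    mu: float


@dataclass
class AttenuationTable:
    """Per-electron channel cross sections on a rectangular (E, Z) grid.

    ``sigma`` maps channel name -> array of shape (n_energies, n_Z).
    """

    energies: np.ndarray
    Z: np.ndarray
    sigma: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.Z = np.asarray(self.Z, dtype=int)
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("table energies must be strictly ascending")
        for ch in CHANNELS:
            if ch not in self.sigma:
                raise ValueError(f"missing channel {ch!r}")
            arr = np.asarray(self.sigma[ch], dtype=float)
            if arr.shape != (self.energies.size, self.Z.size):
                raise ValueError(
                    f"channel {ch!r} has shape {arr.shape}, expected "
                    f"{(self.energies.size, self.Z.size)}"
                )
            if np.any(arr <= 0):
                raise ValueError(f"channel {ch!r} contains non-positive cross sections")
            self.sigma[ch] = arr
        tot = self.mu_over_rhoe_grid
        if np.any(np.diff(tot, axis=0) >= 0):
            warnings.warn(
                "total cross section is not strictly decreasing with energy "
                "for some Z; table may contain absorption edges",
                stacklevel=2,
            )
        self._zindex = {int(z): i for i, z in enumerate(self.Z)}
        self._logE = np.log(self.energies)

    # -- construction / IO -------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AttenuationTable":
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"attenuation table missing columns: {missing}")
        if df.duplicated(subset=["Z", "E_keV"]).any():
            raise ValueError("duplicate (Z, E) rows in attenuation table")
        zs = np.sort(df["Z"].unique())
        es = np.sort(df["E_keV"].unique())
        pivot = {}
        for ch, col in zip(CHANNELS, ["sigma_pe", "sigma_incoh", "sigma_coh"]):
            p = df.pivot(index="E_keV", columns="Z", values=col)
            p = p.reindex(index=es, columns=zs)
            if p.isna().any().any():
                raise ValueError("attenuation table is not a full (Z, E) grid")
            pivot[ch] = p.to_numpy()
        return cls(energies=es, Z=zs, sigma=pivot)

    def to_dataframe(self) -> pd.DataFrame:
        ee, zz = np.meshgrid(self.energies, self.Z, indexing="ij")
        return pd.DataFrame(
            {
                "Z": zz.ravel().astype(int),
                "E_keV": ee.ravel(),
                "sigma_pe": self.sigma["pe"].ravel(),
                "sigma_incoh": self.sigma["incoh"].ravel(),
                "sigma_coh": self.sigma["coh"].ravel(),
            }
        )

    def to_csv(self, path) -> None:
        # repr round-trips float64 exactly
        self.to_dataframe().to_csv(path, index=False, float_format=lambda x: repr(float(x)))

    # -- evaluation --------------------------------------------------------

    @property
    def mu_over_rhoe_grid(self) -> np.ndarray:
        return self.sigma["pe"] + self.sigma["incoh"] + self.sigma["coh"]

    def _col(self, Z: int) -> int:
        try:
            return self._zindex[int(Z)]
        except KeyError as exc:
            raise KeyError(f"element Z={Z} not tabulated") from exc

    def _check_range(self, E) -> np.ndarray:
        E = np.asarray(E, dtype=float)
        if np.any(E < self.energies[0] - 1e-12) or np.any(E > self.energies[-1] + 1e-12):
            raise ValueError(
                f"energy outside table range "
                f"[{self.energies[0]}, {self.energies[-1]}] keV"
            )
        return E

    def _loglog_interp(self, values: np.ndarray, E) -> np.ndarray:
        E = self._check_range(E)
        return np.exp(np.interp(np.log(E), self._logE, np.log(values)))

    def channel(self, name: str, E, Z: int) -> np.ndarray | float:
        """One channel cross section at (E, Z), log-log interpolated in E."""
        out = self._loglog_interp(self.sigma[name][:, self._col(Z)], E)
        return float(out) if np.isscalar(E) or np.ndim(E) == 0 else out


def load_attenuation_table(source) -> AttenuationTable:
    """Read a CSV with header ``Z,E_keV,sigma_pe,sigma_incoh,sigma_coh``."""
    df = pd.read_csv(source, float_precision="round_trip")
    return AttenuationTable.from_dataframe(df)


def mu_over_rhoe(table: AttenuationTable, E, Z: int) -> float | np.ndarray:
    """Total cross section per electron (cm²/electron) at (E, Z).

    Interpolates the summed channel quantity log-log in E; exact at grid
    nodes.  Energies outside the table raise (no extrapolation).
    """
    out = table._loglog_interp(table.mu_over_rhoe_grid[:, table._col(Z)], E)
    return float(out) if np.ndim(E) == 0 else out


def electron_density_per_element(mat: Material) -> list[tuple[int, float]]:
    """Per-element electron densities ρ·N_A·ωᵢZᵢ/Aᵢ (cm⁻³)."""
    comp = mat.composition
    out = []
    for z, w in comp.entries:
        out.append((z, mat.rho * DEFAULT_CONSTANTS.N_A * w * z / ELEMENTS[z].A))
    return out


def mixture_mu(table: AttenuationTable, mat: Material, E) -> float | np.ndarray:
    """Linear attenuation coefficient (cm⁻¹) of a mixture at energy E."""
    total = 0.0
    for z, rhoe_i in electron_density_per_element(mat):
        total = total + rhoe_i * mu_over_rhoe(table, E, z)
    return total


def spectrum_weighted_mu(
    table: AttenuationTable,
    mat: Material,
    spectrum: SpectrumModel,
    window: EnergyWindow,
    step: float = RESAMPLE_STEP_KEV,
) -> float:
    """Fluence-weighted window-average linear attenuation ⟨μ⟩ (cm⁻¹)."""
    w = window_weights(spectrum, window, step)
    mu = mixture_mu(table, mat, w.grid)
    return float(np.trapezoid(mu * w.omega, w.grid))
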
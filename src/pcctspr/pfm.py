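"""Two- and three-parameter-fitting models (two-PFM, three-PFM).

Both methods approximate the per-electron photon cross section σ(E, Z)
of the attenuation table by smooth surfaces and then invert four
window-averaged attenuation values ⟨μ⟩₁..⟨μ⟩₄ into an effective atomic
number Z̄ and an electron density ρe.

Two-PFM (photoelectric + combined scattering)::

    μ(E, Z) = ρe [ Z⁴ F(E, Z) + G(E, Z) ]

F and G are obtained, energy by energy, as quadratic least-squares fits
in Z of σ_pe/Z⁴ and of σ_incoh + σ_coh.  With spectrum weighting the
window coefficients ⟨F⟩k(Z), ⟨G⟩k(Z) remain quadratics whose
coefficients are the fluence-weighted means of the per-energy ones.
Z̄ solves the three adjacent-window conditions

    ⟨μ⟩k·Ak₊₁(Z) − ⟨μ⟩k₊₁·Ak(Z) = 0,   Ak(Z) = Z⁴⟨F⟩k(Z) + ⟨G⟩k(Z),

combined as a least-squares objective (each residual normalised by
⟨μ⟩k⟨μ⟩k₊₁ so it is dimensionless and ρe-free), minimised by a bracketed
grid scan plus golden-section polish on Z ∈ [1, 30].  ρe then solves
⟨μ⟩k = ρe·Ak(Z̄) in the least-squares sense over the four windows.

Three-PFM (photoelectric + incoherent + coherent, with energy- and
Z-dependent coefficients *and* exponents)::

    μ(E, Z) = ρe Σ_c K_c(E, Z)·Z^{p_c(E, Z)}

realised as per-energy quadratic fits of ln σ_c versus ln Z, so each
channel carries a Z-dependent local exponent p_c = ∂lnσ_c/∂lnZ.  The
window response σ_k(Z) is the spectral weighting of the channel sum, and
Z̄ is the root of the four-window determinant condition

    −⟨μ⟩₂σ₁(Z) + (⟨μ⟩₁−⟨μ⟩₃)σ₂(Z) + (⟨μ⟩₂−⟨μ⟩₄)σ₃(Z) + ⟨μ⟩₃σ₄(Z) = 0,

found by a dense-scan bracket plus bisection (ρe cancels).  Finally
ρe = (1/4) Σk ⟨μ⟩k/σk(Z̄).

Both solvers are deterministic and vectorised over batches of pixels.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import json
import numpy as np

from .attenuation import AttenuationTable, CHANNELS, WindowAttenuation
from .spectrum import (
    RESAMPLE_STEP_KEV,
    EnergyWindow,
    SpectrumModel,
    validate_windows,
    window_weights,
)

__all__ = [
    "TwoPFM",
    "ThreePFM",
    "TwoPFMResult",
    "ThreePFMResult",
    "WeightedTwoPFM",
    "WeightedThreePFM",
    "DecompositionResult",
    "fit_two_pfm",
    "fit_three_pfm",
    "weight_model",
    "solve_zeff_two_pfm",
    "solve_rhoe_two_pfm",
    "solve_zeff_three_pfm",
    "solve_rhoe_three_pfm",
    "Z_BRACKET",
]

#: Solver bracket in effective atomic number.
Z_BRACKET = (1.0, 30.0)
_Z_SCAN_STEP = 0.01
_GOLDEN_ITER = 70
_BISECT_ITER = 52
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class DecompositionResult:
    """Outcome of one four-window inversion."""

    zeff: float
    rhoe: float
    converged: bool
    diagnostics: dict


def _as_mu_vector(mu) -> np.ndarray:
    if len(mu) and isinstance(mu[0], WindowAttenuation):
        mu = [m.mu for m in sorted(mu, key=lambda m: m.k)]
    arr = np.asarray(mu, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"expected four window attenuations, got shape {arr.shape}")
    return arr


def _grid_sigmas(table: AttenuationTable, energy_grid: np.ndarray):
    """Channel cross sections at the fit energies, (nE, nZ) per channel."""
    out = {}
    for ch in CHANNELS:
        cols = [
            table._loglog_interp(table.sigma[ch][:, j], energy_grid)
            for j in range(table.Z.size)
        ]
        out[ch] = np.column_stack(cols)
    return out


def _quad_design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x, x * x])


def _interp_coefs(energy_grid: np.ndarray, coefs: np.ndarray, E) -> np.ndarray:
    """Linear-in-E interpolation of per-energy fit coefficients, (..., 3)."""
    E = np.atleast_1d(np.asarray(E, dtype=float))
    if np.any(E < energy_grid[0] - 1e-9) or np.any(E > energy_grid[-1] + 1e-9):
        raise ValueError("energy outside fitted grid")
    return np.column_stack([np.interp(E, energy_grid, coefs[:, j]) for j in range(3)])


# ===========================================================================
# Two-PFM
# ===========================================================================


class TwoPFM:
    """Two-parameter-fitting model of an attenuation table.

    Parameters
    ----------
    table:
        Per-electron channel cross-section table (Z = 1..29 expected).
    energy_grid:
        Energies (keV) at which the per-energy quadratic fits are made;
        defaults to the table's own grid.
    """

    def __init__(self, table: AttenuationTable, energy_grid=None):
        self.table = table
        self.energy_grid = (
            np.asarray(energy_grid, dtype=float)
            if energy_grid is not None
            else table.energies.copy()
        )

    def fit(self) -> "TwoPFMResult":
        sig = _grid_sigmas(self.table, self.energy_grid)
        z = self.table.Z.astype(float)
        X = _quad_design(z)
        y_f = sig["pe"] / z[None, :] ** 4
        y_g = sig["incoh"] + sig["coh"]
        f_coefs, *_ = np.linalg.lstsq(X, y_f.T, rcond=None)
        g_coefs, *_ = np.linalg.lstsq(X, y_g.T, rcond=None)
        f_coefs, g_coefs = f_coefs.T, g_coefs.T  # (nE, 3)
        recon = (X @ f_coefs.T).T * z[None, :] ** 4 + (X @ g_coefs.T).T
        total = sum(sig[ch] for ch in CHANNELS)
        rel_err = (recon - total) / total
        return TwoPFMResult(
            energy_grid=self.energy_grid,
            Z=self.table.Z.copy(),
            f_coefs=f_coefs,
            g_coefs=g_coefs,
            rel_err=rel_err,
        )


@dataclass
class TwoPFMResult:
    """Fitted F/G surfaces plus reconstruction-error diagnostics."""

    energy_grid: np.ndarray
    Z: np.ndarray
    f_coefs: np.ndarray  # (nE, 3) quadratic-in-Z coefficients of F
    g_coefs: np.ndarray  # (nE, 3)
    rel_err: np.ndarray  # (nE, nZ) relative reconstruction error on the grid

    @property
    def max_rel_error(self) -> float:
        return float(np.max(np.abs(self.rel_err)))

    def F(self, E, Z) -> np.ndarray | float:
        c = _interp_coefs(self.energy_grid, self.f_coefs, E)
        Z = np.asarray(Z, dtype=float)
        out = c[:, 0] + c[:, 1] * Z + c[:, 2] * Z * Z
        return float(out[0]) if out.size == 1 else out

    def G(self, E, Z) -> np.ndarray | float:
        c = _interp_coefs(self.energy_grid, self.g_coefs, E)
        Z = np.asarray(Z, dtype=float)
        out = c[:, 0] + c[:, 1] * Z + c[:, 2] * Z * Z
        return float(out[0]) if out.size == 1 else out

    def mu_over_rhoe(self, E, Z) -> np.ndarray | float:
        """Reconstructed per-electron cross section Z⁴F + G (cm²/electron)."""
        Zf = np.asarray(Z, dtype=float)
        return self.F(E, Z) * Zf**4 + self.G(E, Z)

    def weighted(
        self,
        spectrum: SpectrumModel,
        windows: Sequence[EnergyWindow],
        step: float = RESAMPLE_STEP_KEV,
    ) -> "WeightedTwoPFM":
        """Spectrum-weighted window coefficients ⟨F⟩k, ⟨G⟩k.

        Because F and G are quadratics in Z with energy-dependent
        coefficients, the fluence-weighted window average acts on the
        coefficients alone (the weighting is linear), so ⟨F⟩k and ⟨G⟩k
        are again exact quadratics in Z.
        """
        validate_windows(windows)
        Fk, Gk = [], []
        for win in windows:
            w = window_weights(spectrum, win, step)
            cf = _interp_coefs(self.energy_grid, self.f_coefs, w.grid)
            cg = _interp_coefs(self.energy_grid, self.g_coefs, w.grid)
            Fk.append(np.trapezoid(cf * w.omega[:, None], w.grid, axis=0))
            Gk.append(np.trapezoid(cg * w.omega[:, None], w.grid, axis=0))
        return WeightedTwoPFM(
            windows=tuple(windows), Fk=np.array(Fk), Gk=np.array(Gk), parent=self
        )

    def at_energies(self, energies: Sequence[float]) -> "WeightedTwoPFM":
        """Monochromatic coefficients: the delta-spectrum limit of
        :meth:`weighted`, one energy per window."""
        energies = np.asarray(energies, dtype=float)
        Fk = _interp_coefs(self.energy_grid, self.f_coefs, energies)
        Gk = _interp_coefs(self.energy_grid, self.g_coefs, energies)
        windows = tuple(
            EnergyWindow(k + 1, e - 1e-6, e + 1e-6) for k, e in enumerate(energies)
        )
        return WeightedTwoPFM(windows=windows, Fk=Fk, Gk=Gk, parent=self)

    # -- serialisation -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "model": "two-pfm",
            "energy_grid": self.energy_grid.tolist(),
            "Z": self.Z.tolist(),
            "f_coefs": self.f_coefs.tolist(),
            "g_coefs": self.g_coefs.tolist(),
            "rel_err": self.rel_err.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TwoPFMResult":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("model") != "two-pfm":
            raise ValueError("not a serialised two-PFM model")
        return cls(
            energy_grid=np.array(payload["energy_grid"]),
            Z=np.array(payload["Z"], dtype=int),
            f_coefs=np.array(payload["f_coefs"]),
            g_coefs=np.array(payload["g_coefs"]),
            rel_err=np.array(payload["rel_err"]),
        )

    def summary(self) -> str:
        lines = [
            "Two-parameter-fitting model (mu/rhoe = Z^4 F(E,Z) + G(E,Z))",
            f"  energy grid : {self.energy_grid[0]:.1f}-{self.energy_grid[-1]:.1f} keV "
            f"({self.energy_grid.size} points)",
            f"  Z range     : {self.Z.min()}-{self.Z.max()}",
            f"  max |relative reconstruction error| : {self.max_rel_error:.3e}",
        ]
        return "\n".join(lines)


@dataclass
class WeightedTwoPFM:
    """Two-PFM with per-window coefficients ready for inversion."""

    windows: tuple[EnergyWindow, ...]
    Fk: np.ndarray  # (4, 3)
    Gk: np.ndarray  # (4, 3)
    parent: TwoPFMResult | None = None

    def __post_init__(self) -> None:
        if self.Fk.shape != (4, 3) or self.Gk.shape != (4, 3):
            raise ValueError("expected four windows of quadratic coefficients")

    def A(self, k: int, Z: np.ndarray) -> np.ndarray:
        """Per-electron window response Ak(Z) = Z⁴⟨F⟩k(Z) + ⟨G⟩k(Z)."""
        Z = np.asarray(Z, dtype=float)
        f = self.Fk[k, 0] + self.Fk[k, 1] * Z + self.Fk[k, 2] * Z * Z
        g = self.Gk[k, 0] + self.Gk[k, 1] * Z + self.Gk[k, 2] * Z * Z
        return Z**4 * f + g

    # -- solvers -----------------------------------------------------------

    def _objective(self, mu: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """Sum of squared normalised adjacent-window residuals.

        mu: (4, N), Z: (N,) -> (N,)
        """
        obj = np.zeros(Z.shape)
        terms = [self.A(k, Z) / mu[k] for k in range(4)]
        for k in range(3):
            r = terms[k + 1] - terms[k]
            obj += r * r
        return obj

    def solve_batch(self, mu: np.ndarray):
        """Vectorised inversion of many pixels.

        Parameters
        ----------
        mu : array (4, N) of window attenuations (cm⁻¹).

        Returns
        -------
        zeff, rhoe, valid : arrays (N,)
        """
        mu = np.asarray(mu, dtype=float)
        if mu.ndim != 2 or mu.shape[0] != 4:
            raise ValueError("mu must have shape (4, N)")
        n = mu.shape[1]
        valid = np.all(np.isfinite(mu), axis=0) & np.all(mu > 0, axis=0)
        zeff = np.full(n, np.nan)
        rhoe = np.full(n, np.nan)
        if not np.any(valid):
            return zeff, rhoe, valid
        mv = mu[:, valid]

        zgrid = np.arange(Z_BRACKET[0], Z_BRACKET[1] + _Z_SCAN_STEP / 2, _Z_SCAN_STEP)
        agrid = np.stack([self.A(k, zgrid) for k in range(4)])  # (4, M)
        # coarse scan, chunked to bound memory
        best = np.empty(mv.shape[1], dtype=int)
        for lo in range(0, mv.shape[1], 1024):
            sl = slice(lo, min(lo + 1024, mv.shape[1]))
            obj = np.zeros((sl.stop - sl.start, zgrid.size))
            terms = [agrid[k][None, :] / mv[k, sl][:, None] for k in range(4)]
            for k in range(3):
                r = terms[k + 1] - terms[k]
                obj += r * r
            best[sl] = np.argmin(obj, axis=1)
        a = np.clip(zgrid[np.maximum(best - 1, 0)], *Z_BRACKET)
        b = np.clip(zgrid[np.minimum(best + 1, zgrid.size - 1)], *Z_BRACKET)
        # golden-section polish (deterministic, derivative-free)
        for _ in range(_GOLDEN_ITER):
            c = b - _INVPHI * (b - a)
            d = a + _INVPHI * (b - a)
            fc = self._objective(mv, c)
            fd = self._objective(mv, d)
            take_left = fc < fd
            b = np.where(take_left, d, b)
            a = np.where(take_left, a, c)
        zv = 0.5 * (a + b)
        zeff[valid] = zv
        rhoe[valid] = self._rhoe_lsq(mv, zv)
        return zeff, rhoe, valid

    def _rhoe_lsq(self, mu: np.ndarray, zeff: np.ndarray) -> np.ndarray:
        A = np.stack([self.A(k, zeff) for k in range(4)])  # (4, N)
        return np.sum(A * mu, axis=0) / np.sum(A * A, axis=0)

    def solve_zeff(self, mu) -> DecompositionResult:
        muv = _as_mu_vector(mu)
        z, r, valid = self.solve_batch(muv[:, None])
        obj = float(self._objective(muv[:, None], np.array([z[0]]))[0]) if valid[0] else np.inf
        return DecompositionResult(
            zeff=float(z[0]),
            rhoe=float(r[0]),
            converged=bool(valid[0]),
            diagnostics={"objective": obj, "method": "two-pfm"},
        )

    def solve_rhoe(self, mu, zeff: float, method: str = "lsq") -> float:
        """Electron density given Z̄.

        ``method="lsq"`` (default): least-squares over the four windows of
        ⟨μ⟩k = ρe·Ak(Z̄) — exact on model-consistent input.
        ``method="literal"``: the printed adjacent/k+2 two-window form,
        averaged over the valid window triplets; kept for comparison only
        (it is not exact even on noiseless model-consistent data).
        """
        muv = _as_mu_vector(mu)
        if method == "lsq":
            return float(self._rhoe_lsq(muv[:, None], np.array([zeff]))[0])
        if method == "literal":
            z = float(zeff)
            f = [float(self.Fk[k, 0] + self.Fk[k, 1] * z + self.Fk[k, 2] * z * z) for k in range(4)]
            g = [float(self.Gk[k, 0] + self.Gk[k, 1] * z + self.Gk[k, 2] * z * z) for k in range(4)]
            vals = []
            for k in range(2):  # k, k+1, k+2 within the four windows
                denom = f[k + 1] * g[k] - f[k] * g[k + 2]
                if denom == 0:
                    raise ZeroDivisionError("degenerate model in literal rhoe form")
                vals.append((f[k + 1] * muv[k] - f[k] * muv[k + 2]) / denom)
            return float(np.mean(vals))
        raise ValueError(f"unknown rhoe method {method!r}")


# ===========================================================================
# Three-PFM
# ===========================================================================


class ThreePFM:
    """Three-parameter-fitting model with E- and Z-dependent exponents."""

    def __init__(self, table: AttenuationTable, energy_grid=None):
        self.table = table
        self.energy_grid = (
            np.asarray(energy_grid, dtype=float)
            if energy_grid is not None
            else table.energies.copy()
        )

    def fit(self) -> "ThreePFMResult":
        sig = _grid_sigmas(self.table, self.energy_grid)
        lz = np.log(self.table.Z.astype(float))
        X = _quad_design(lz)
        coefs = {}
        recon_total = 0.0
        for ch in CHANNELS:
            c, *_ = np.linalg.lstsq(X, np.log(sig[ch]).T, rcond=None)
            coefs[ch] = c.T  # (nE, 3)
            recon_total = recon_total + np.exp((X @ c).T)
        total = sum(sig[ch] for ch in CHANNELS)
        rel_err = (recon_total - total) / total
        channel_rel_err = {
            ch: (np.exp((_quad_design(lz) @ coefs[ch].T).T) - sig[ch]) / sig[ch]
            for ch in CHANNELS
        }
        return ThreePFMResult(
            energy_grid=self.energy_grid,
            Z=self.table.Z.copy(),
            coefs=coefs,
            rel_err=rel_err,
            channel_rel_err=channel_rel_err,
        )


@dataclass
class ThreePFMResult:
    """Per-channel ln σ = q₀ + q₁ lnZ + q₂ (lnZ)² surfaces."""

    energy_grid: np.ndarray
    Z: np.ndarray
    coefs: dict[str, np.ndarray]  # channel -> (nE, 3)
    rel_err: np.ndarray  # (nE, nZ), total reconstruction
    channel_rel_err: dict[str, np.ndarray]

    @property
    def max_rel_error(self) -> float:
        return float(np.max(np.abs(self.rel_err)))

    def channel_sigma(self, ch: str, E, Z) -> np.ndarray | float:
        c = _interp_coefs(self.energy_grid, self.coefs[ch], E)
        lz = np.log(np.asarray(Z, dtype=float))
        out = np.exp(c[:, 0] + c[:, 1] * lz + c[:, 2] * lz * lz)
        return float(out[0]) if out.size == 1 else out

    def exponent(self, ch: str, E, Z) -> np.ndarray | float:
        """Local Z-exponent p_c(E,Z) = ∂ ln σ_c / ∂ ln Z."""
        c = _interp_coefs(self.energy_grid, self.coefs[ch], E)
        lz = np.log(np.asarray(Z, dtype=float))
        out = c[:, 1] + 2.0 * c[:, 2] * lz
        return float(out[0]) if out.size == 1 else out

    def mu_over_rhoe(self, E, Z) -> np.ndarray | float:
        return sum(self.channel_sigma(ch, E, Z) for ch in CHANNELS)

    def weighted(
        self,
        spectrum: SpectrumModel,
        windows: Sequence[EnergyWindow],
        step: float = RESAMPLE_STEP_KEV,
    ) -> "WeightedThreePFM":
        """Spectrum-weighted window responses σk(Z) by quadrature."""
        validate_windows(windows)
        grids, weights, coef_sets = [], [], []
        for win in windows:
            w = window_weights(spectrum, win, step)
            # trapezoid quadrature weights: dx*(1/2,1,...,1,1/2)
            dx = w.grid[1] - w.grid[0]
            q = np.full(w.grid.size, dx)
            q[0] = q[-1] = dx / 2
            q = q * w.omega
            q = q / q.sum()
            grids.append(w.grid)
            weights.append(q)
            coef_sets.append(
                {ch: _interp_coefs(self.energy_grid, self.coefs[ch], w.grid) for ch in CHANNELS}
            )
        return WeightedThreePFM(
            windows=tuple(windows),
            grids=grids,
            weights=weights,
            coef_sets=coef_sets,
            parent=self,
        )

    def at_energies(self, energies: Sequence[float]) -> "WeightedThreePFM":
        """Monochromatic responses: the delta-spectrum limit."""
        energies = np.asarray(energies, dtype=float)
        grids = [np.array([e]) for e in energies]
        weights = [np.array([1.0]) for _ in energies]
        coef_sets = [
            {ch: _interp_coefs(self.energy_grid, self.coefs[ch], np.array([e])) for ch in CHANNELS}
            for e in energies
        ]
        windows = tuple(
            EnergyWindow(k + 1, e - 1e-6, e + 1e-6) for k, e in enumerate(energies)
        )
        return WeightedThreePFM(
            windows=windows, grids=grids, weights=weights, coef_sets=coef_sets, parent=self
        )

    def to_json(self, path) -> None:
        payload = {
            "model": "three-pfm",
            "energy_grid": self.energy_grid.tolist(),
            "Z": self.Z.tolist(),
            "coefs": {ch: c.tolist() for ch, c in self.coefs.items()},
            "rel_err": self.rel_err.tolist(),
            "channel_rel_err": {ch: c.tolist() for ch, c in self.channel_rel_err.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ThreePFMResult":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("model") != "three-pfm":
            raise ValueError("not a serialised three-PFM model")
        return cls(
            energy_grid=np.array(payload["energy_grid"]),
            Z=np.array(payload["Z"], dtype=int),
            coefs={ch: np.array(c) for ch, c in payload["coefs"].items()},
            rel_err=np.array(payload["rel_err"]),
            channel_rel_err={ch: np.array(c) for ch, c in payload["channel_rel_err"].items()},
        )

    def summary(self) -> str:
        lines = [
            "Three-parameter-fitting model (per-channel ln sigma quadratic in ln Z)",
            f"  energy grid : {self.energy_grid[0]:.1f}-{self.energy_grid[-1]:.1f} keV "
            f"({self.energy_grid.size} points)",
            f"  Z range     : {self.Z.min()}-{self.Z.max()}",
            f"  max |relative reconstruction error| : {self.max_rel_error:.3e}",
        ]
        for ch in CHANNELS:
            lines.append(
                f"    channel {ch:6s}: max |rel err| = "
                f"{np.max(np.abs(self.channel_rel_err[ch])):.3e}"
            )
        return "\n".join(lines)


@dataclass
class WeightedThreePFM:
    """Three-PFM with per-window spectral response σk(Z)."""

    windows: tuple[EnergyWindow, ...]
    grids: list[np.ndarray]
    weights: list[np.ndarray]
    coef_sets: list[dict[str, np.ndarray]]
    parent: ThreePFMResult | None = None

    def __post_init__(self) -> None:
        if len(self.windows) != 4:
            raise ValueError("three-PFM inversion needs exactly four windows")
        self._dense_cache = None

    def response(self, k: int, Z) -> np.ndarray:
        """σk(Z): spectrum-weighted per-electron cross section, window k."""
        Z = np.atleast_1d(np.asarray(Z, dtype=float))
        lz = np.log(Z)
        lz2 = lz * lz
        total = np.zeros(Z.shape)
        q = self.weights[k]
        for ch in CHANNELS:
            c = self.coef_sets[k][ch]  # (nE, 3)
            ln_sig = c[:, 0][:, None] + c[:, 1][:, None] * lz[None, :] + c[:, 2][:, None] * lz2[None, :]
            total += q @ np.exp(ln_sig)
        return total

    def _dense(self):
        if self._dense_cache is None:
            zgrid = np.arange(Z_BRACKET[0], Z_BRACKET[1] + _Z_SCAN_STEP / 2, _Z_SCAN_STEP)
            sgrid = np.stack([self.response(k, zgrid) for k in range(4)])
            self._dense_cache = (zgrid, sgrid)
        return self._dense_cache

    def _residual_coefs(self, mu: np.ndarray) -> np.ndarray:
        """Coefficients c (4, N) of the root condition Σk ck·σk(Z) = 0."""
        return np.stack([-mu[1], mu[0] - mu[2], mu[1] - mu[3], mu[2]])

    def solve_batch(self, mu: np.ndarray):
        """Vectorised inversion; see :meth:`WeightedTwoPFM.solve_batch`."""
        mu = np.asarray(mu, dtype=float)
        if mu.ndim != 2 or mu.shape[0] != 4:
            raise ValueError("mu must have shape (4, N)")
        n = mu.shape[1]
        valid = np.all(np.isfinite(mu), axis=0) & np.all(mu > 0, axis=0)
        zeff = np.full(n, np.nan)
        rhoe = np.full(n, np.nan)
        if not np.any(valid):
            return zeff, rhoe, valid
        mv = mu[:, valid]
        cc = self._residual_coefs(mv)  # (4, Nv)
        zgrid, sgrid = self._dense()
        nv = mv.shape[1]
        # collect every sign-change interval of the dense scan; noisy
        # inputs can produce more than one root, so all candidates are
        # polished and the physically consistent one selected below
        pix_parts, itv_parts = [], []
        for start in range(0, nv, 1024):
            sl = slice(start, min(start + 1024, nv))
            g = cc[:, sl].T @ sgrid  # (chunk, M)
            pi, ii = np.nonzero(g[:, :-1] * g[:, 1:] <= 0)
            pix_parts.append(pi + start)
            itv_parts.append(ii)
        pix = np.concatenate(pix_parts) if pix_parts else np.empty(0, dtype=int)
        itv = np.concatenate(itv_parts) if itv_parts else np.empty(0, dtype=int)
        zeff_v = np.full(nv, np.nan)
        rhoe_v = np.full(nv, np.nan)
        found = np.zeros(nv, dtype=bool)
        if pix.size:
            a = zgrid[itv].copy()
            b = zgrid[itv + 1].copy()
            cp = cc[:, pix]
            ga = self._residual_at(cp, a)
            for _ in range(_BISECT_ITER):
                m = 0.5 * (a + b)
                gm = self._residual_at(cp, m)
                left = (ga * gm) <= 0
                b = np.where(left, m, b)
                a = np.where(left, a, m)
                ga = np.where(left, ga, gm)
            root = 0.5 * (a + b)
            sroot = np.stack([self.response(k, root) for k in range(4)])  # (4, C)
            ratios = mv[:, pix] / sroot
            mean_r = np.mean(ratios, axis=0)
            # candidate quality: spread of the four per-window densities
            # mu_k/sigma_k(Z) — zero at a true root of consistent data
            cv = np.std(ratios, axis=0) / np.where(mean_r > 0, mean_r, np.inf)
            cv = np.where(mean_r > 0, cv, np.inf)
            order = np.lexsort((cv, pix))  # by pixel, best candidate first
            first = np.ones(order.size, dtype=bool)
            first[1:] = pix[order][1:] != pix[order][:-1]
            sel = order[first]
            keep = np.isfinite(cv[sel])
            sel = sel[keep]
            found[pix[sel]] = True
            zeff_v[pix[sel]] = root[sel]
            rhoe_v[pix[sel]] = mean_r[sel]
        out_valid = valid.copy()
        out_valid[np.where(valid)[0][~found]] = False
        zeff[valid] = zeff_v
        rhoe[valid] = rhoe_v
        return zeff, rhoe, out_valid

    def _residual_at(self, cc: np.ndarray, Z: np.ndarray) -> np.ndarray:
        s = np.stack([self.response(k, Z) for k in range(4)])  # (4, N)
        return np.sum(cc * s, axis=0)

    def solve_zeff(self, mu) -> DecompositionResult:
        muv = _as_mu_vector(mu)
        z, r, valid = self.solve_batch(muv[:, None])
        if not valid[0]:
            return DecompositionResult(
                zeff=np.nan,
                rhoe=np.nan,
                converged=False,
                diagnostics={
                    "method": "three-pfm",
                    "reason": "no sign change of the root condition in "
                    f"Z in [{Z_BRACKET[0]}, {Z_BRACKET[1]}]",
                },
            )
        res = float(self._residual_at(self._residual_coefs(muv[:, None]), np.array([z[0]]))[0])
        return DecompositionResult(
            zeff=float(z[0]),
            rhoe=float(r[0]),
            converged=True,
            diagnostics={"residual": res, "method": "three-pfm"},
        )

    def solve_rhoe(self, mu, zeff: float) -> float:
        """Four-window mean of ⟨μ⟩k / σk(Z̄)."""
        muv = _as_mu_vector(mu)
        s = np.array([float(self.response(k, np.array([zeff]))[0]) for k in range(4)])
        if np.any(s <= 0):
            raise ZeroDivisionError("degenerate window response in three-PFM")
        return float(np.mean(muv / s))


# ===========================================================================
# Operation-style wrappers
# ===========================================================================


def fit_two_pfm(table: AttenuationTable, energy_grid=None) -> TwoPFMResult:
    return TwoPFM(table, energy_grid).fit()


def fit_three_pfm(table: AttenuationTable, energy_grid=None) -> ThreePFMResult:
    return ThreePFM(table, energy_grid).fit()


def weight_model(model, spectrum: SpectrumModel, windows: Sequence[EnergyWindow]):
    """Attach spectrum-weighted window coefficients to a fitted model."""
    return model.weighted(spectrum, windows)


def solve_zeff_two_pfm(mu, model: WeightedTwoPFM) -> DecompositionResult:
    return model.solve_zeff(mu)


def solve_rhoe_two_pfm(mu, zeff: float, model: WeightedTwoPFM, method: str = "lsq") -> float:
    return model.solve_rhoe(mu, zeff, method=method)


def solve_zeff_three_pfm(mu, model: WeightedThreePFM) -> DecompositionResult:
    return model.solve_zeff(mu)


def solve_rhoe_three_pfm(mu, zeff: float, model: WeightedThreePFM) -> float:
    return model.solve_rhoe(mu, zeff)
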
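"""Semi-empirical CT-number correction.

Linear attenuation coefficients measured with a CdTe counting detector
fall below their theoretical (reference cross-section) values because of
scattered photons and inter-pixel charge sharing.  Rather than modelling
those mechanisms, each energy window k gets an empirical power-law map

    μ_corrected = a_k · μ_measured^{b_k}

fitted in log-log space (ln μ_expected = ln a_k + b_k ln μ_measured) to a
set of calibration rods whose expected window attenuations come from the
spectrum-weighted theoretical values.  The correction is strictly
increasing, so pixel ordering is preserved.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["CorrectionModel", "PowerLawCorrection", "fit_correction", "apply_correction"]


@dataclass
class CorrectionModel:
    """Per-window power-law coefficients and fit diagnostics."""

    a: np.ndarray  # (n_windows,)
    b: np.ndarray  # (n_windows,)
    r_squared: np.ndarray  # (n_windows,) in log-log space
    materials: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if np.any(self.a <= 0):
            raise ValueError("power-law prefactors a_k must be positive")
        if np.any(self.b <= 0):
            raise ValueError("power-law exponents b_k must be positive for monotonicity")

    @property
    def n_windows(self) -> int:
        return self.a.size

    def apply(self, mu: np.ndarray, k: int):
        """Apply window k's correction element-wise; zeros map to zero,
        negative inputs are clamped to zero (count available via
        :func:`apply_correction`)."""
        mu = np.asarray(mu, dtype=float)
        out = np.zeros_like(mu)
        pos = mu > 0
        out[pos] = self.a[k] * mu[pos] ** self.b[k]
        return out

    def to_json(self, path) -> None:
        payload = {
            f"window_{k + 1}": {"a": float(self.a[k]), "b": float(self.b[k])}
            for k in range(self.n_windows)
        }
        payload["materials"] = list(self.materials)
        payload["r_squared"] = self.r_squared.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CorrectionModel":
        with open(path) as fh:
            payload = json.load(fh)
        ks = sorted(int(k.split("_")[1]) for k in payload if k.startswith("window_"))
        a = np.array([payload[f"window_{k}"]["a"] for k in ks])
        b = np.array([payload[f"window_{k}"]["b"] for k in ks])
        r2 = np.array(payload.get("r_squared", [np.nan] * len(ks)))
        return cls(a=a, b=b, r_squared=r2, materials=tuple(payload.get("materials", ())))


class PowerLawCorrection:
    """Model object fitting the per-window power-law calibration.

    Parameters
    ----------
    measured, expected:
        Arrays of shape (n_materials, n_windows) of positive window
        attenuations (cm⁻¹): the measured rod values and the
        theoretical spectrum-weighted values.
    materials:
        Optional material labels for provenance.
    """

    def __init__(self, measured, expected, materials=()):
        self.measured = np.asarray(measured, dtype=float)
        self.expected = np.asarray(expected, dtype=float)
        if self.measured.shape != self.expected.shape:
            raise ValueError("measured and expected must have the same shape")
        if self.measured.ndim != 2:
            raise ValueError("expected (n_materials, n_windows) arrays")
        if self.measured.shape[0] < 3:
            raise ValueError("need at least 3 calibration materials per window")
        if np.any(self.measured <= 0) or np.any(self.expected <= 0):
            raise ValueError("calibration attenuations must be positive")
        self.materials = tuple(materials)

    def fit(self) -> CorrectionModel:
        n_win = self.measured.shape[1]
        a = np.empty(n_win)
        b = np.empty(n_win)
        r2 = np.empty(n_win)
        for k in range(n_win):
            x = np.log(self.measured[:, k])
            y = np.log(self.expected[:, k])
            X = np.column_stack([np.ones_like(x), x])
            (lna, bk), *_ = np.linalg.lstsq(X, y, rcond=None)
            a[k] = np.exp(lna)
            b[k] = bk
            resid = y - X @ [lna, bk]
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2[k] = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        return CorrectionModel(a=a, b=b, r_squared=r2, materials=self.materials)


def fit_correction(measured, expected, materials=()) -> CorrectionModel:
    """Least-squares power-law calibration per window (log-log space)."""
    return PowerLawCorrection(measured, expected, materials).fit()


def apply_correction(model: CorrectionModel, images):
    """Correct a four-window image set (returns a new set).

    Negative pixels are clamped to zero; the clamp count is recorded on
    the returned object as ``n_clamped``.
    """
    from .pipeline import WindowImageSet  # local import to avoid a cycle

    if not isinstance(images, WindowImageSet):
        raise TypeError("images must be a WindowImageSet")
    if len(images.windows) != model.n_windows:
        raise ValueError(
            f"model has {model.n_windows} windows, images have {len(images.windows)}"
        )
    n_clamped = int(np.sum(images.stack < 0))
    corrected = np.stack([model.apply(images.stack[k], k) for k in range(model.n_windows)])
    out = WindowImageSet(
        stack=corrected, windows=images.windows, pixel_size_mm=images.pixel_size_mm
    )
    out.n_clamped = n_clamped
    return out
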
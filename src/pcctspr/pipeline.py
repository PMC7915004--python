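"""Per-pixel map production and ROI statistics.

Takes four co-registered window-attenuation images, optionally applies
the semi-empirical correction, inverts every pixel with a weighted
two- or three-PFM, converts Z̄ to I through the fitted quartic, and
evaluates the Bethe–Bloch stopping-power ratio — yielding co-registered
Z̄, ρe, I and SPR maps plus a validity mask.  Pixels whose inversion
does not converge (e.g. zero attenuation outside the phantom, or no
root of the three-PFM condition) are masked, never filled with fallback
values.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import ME_C2_KEV
from .correction import CorrectionModel, apply_correction
from .pfm import WeightedThreePFM, WeightedTwoPFM
from .spectrum import EnergyWindow
from .spr import BeamSpec, IvalueCurve, spr_bethe

__all__ = [
    "WindowImageSet",
    "DecomposedMaps",
    "RoiStat",
    "decompose_images",
    "roi_stats",
    "mu_to_hounsfield",
    "hounsfield_to_mu",
]


@dataclass
class WindowImageSet:
    """Four co-registered 2-D linear-attenuation images (cm⁻¹)."""

    stack: np.ndarray  # (4, H, W)
    windows: tuple[EnergyWindow, ...]
    pixel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=float)
        if self.stack.ndim != 3 or self.stack.shape[0] != len(self.windows):
            raise ValueError(
                f"stack shape {self.stack.shape} does not match "
                f"{len(self.windows)} windows"
            )
        if len(self.windows) != 4:
            raise ValueError("expected exactly four energy windows")

    @property
    def shape(self) -> tuple[int, int]:
        return self.stack.shape[1:]

    # TIFF I/O: float32 single-channel stack, one page per window,
    # pixel (0, 0) top-left, row-major.
    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.stack.astype(np.float32), photometric="minisblack")

    @classmethod
    def from_tiff(cls, path, windows, pixel_size_mm: float = 1.0) -> "WindowImageSet":
        import tifffile

        stack = np.asarray(tifffile.imread(path), dtype=float)
        return cls(stack=stack, windows=tuple(windows), pixel_size_mm=pixel_size_mm)


@dataclass
class DecomposedMaps:
    """Z̄, ρe, I and SPR maps with a per-pixel validity mask."""

    zeff: np.ndarray
    rhoe: np.ndarray
    ivalue: np.ndarray
    spr: np.ndarray
    valid: np.ndarray  # bool mask
    method: str
    n_masked: int = 0

    def __post_init__(self) -> None:
        self.n_masked = int(self.valid.size - np.count_nonzero(self.valid))


@dataclass
class RoiStat:
    """Mean/std over one ROI with the relative error against theory."""

    label: str
    quantity: str
    mean: float
    std: float
    n: int
    theory: float | None = None

    @property
    def relative_error_pct(self) -> float | None:
        if self.theory is None:
            return None
        return (self.mean - self.theory) / self.theory * 100.0


def decompose_images(
    images: WindowImageSet,
    model: WeightedTwoPFM | WeightedThreePFM,
    correction: CorrectionModel | None = None,
    beam: BeamSpec | None = None,
    curve: IvalueCurve | None = None,
    water_ref: tuple[float, float] | None = None,
) -> DecomposedMaps:
    """Full per-pixel chain: correction → Z̄ → ρe → I → SPR.

    The I and SPR maps are produced only when ``curve``, ``beam`` and
    ``water_ref`` are all given; otherwise they are NaN.
    """
    if tuple(w.k for w in images.windows) != tuple(w.k for w in model.windows):
        raise ValueError("window indices of images and model do not match")
    if correction is not None:
        images = apply_correction(correction, images)
    h, w = images.shape
    mu = images.stack.reshape(4, -1)
    if isinstance(model, (WeightedTwoPFM, WeightedThreePFM)):
        zeff, rhoe, valid = model.solve_batch(mu)
    else:  # pragma: no cover - defensive
        raise TypeError("model must be a weighted two- or three-PFM")
    ivalue = np.full_like(zeff, np.nan)
    sprmap = np.full_like(zeff, np.nan)
    if curve is not None and beam is not None and water_ref is not None:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # extrapolation warnings per-pixel
            ivalue[valid] = np.polyval(curve.coeffs, zeff[valid])
        bad_i = valid & ~(ivalue > 0)
        valid = valid & ~bad_i
        rhoe_w, i_w = water_ref
        beta = beam.beta
        b2 = beta * beta
        me = ME_C2_KEV * 1e3
        num = np.log(2 * me * b2 / (ivalue[valid] * (1 - b2))) - b2
        den = np.log(2 * me * b2 / (i_w * (1 - b2))) - b2
        sprmap[valid] = rhoe[valid] / rhoe_w * num / den
    valid = valid & np.isfinite(zeff) & (rhoe > 0)
    shape = (h, w)
    return DecomposedMaps(
        zeff=zeff.reshape(shape),
        rhoe=rhoe.reshape(shape),
        ivalue=ivalue.reshape(shape),
        spr=sprmap.reshape(shape),
        valid=valid.reshape(shape),
        method="two-pfm" if isinstance(model, WeightedTwoPFM) else "three-pfm",
    )


_QUANTITIES = ("zeff", "rhoe", "ivalue", "spr")


def roi_stats(
    maps: DecomposedMaps,
    rois: Mapping[str, np.ndarray],
    theory: Mapping[str, Mapping[str, float]] | None = None,
) -> list[RoiStat]:
    """Mean/std per ROI and quantity, with Eq-style relative error (%)
    against supplied theory values: (value − theory)/theory × 100."""
    out: list[RoiStat] = []
    for label, mask in rois.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != maps.valid.shape:
            raise ValueError(f"ROI {label!r} shape does not match maps")
        sel = mask & maps.valid
        n = int(np.count_nonzero(sel))
        if n == 0:
            raise ValueError(f"ROI {label!r} contains no valid pixels")
        for q in _QUANTITIES:
            vals = getattr(maps, q)[sel]
            if np.all(np.isnan(vals)):
                continue
            ref = None
            if theory is not None and label in theory and q in theory[label]:
                ref = float(theory[label][q])
            out.append(
                RoiStat(
                    label=label,
                    quantity=q,
                    mean=float(np.nanmean(vals)),
                    std=float(np.nanstd(vals)),
                    n=n,
                    theory=ref,
                )
            )
    return out


def mu_to_hounsfield(mu: np.ndarray, mu_water: float) -> np.ndarray:
    """HU = 1000·(μ − μw)/μw, per window (documented I/O option)."""
    return 1000.0 * (np.asarray(mu, dtype=float) - mu_water) / mu_water


def hounsfield_to_mu(hu: np.ndarray, mu_water: float) -> np.ndarray:
    return (np.asarray(hu, dtype=float) / 1000.0 + 1.0) * mu_water
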
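"""Lorentzian difference analysis of B0-corrected Z-spectra.

A single Lorentzian reference line models direct water saturation plus a
constant background:

    Zref(dw) = c - a * (b^2/4) / (b^2/4 + dw^2)

with amplitude ``a``, width ``b`` (which equals the full width at half
maximum of the dip, in ppm) and background level ``c``.  The residual
magnetization transfer ratio ``MTRres = Zref - Z`` isolates exchange
(CEST) signal from the symmetric water line; its integral over the
0.5-2 ppm hydroxyl band is the Lorentzian-difference glucoCEST contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .pipeline import DEFAULT_BAND, MTRasymResult, ProcessedZSpectrum

__all__ = ["LorentzianFitResult", "lorentzian_ref", "fit_lorentzian", "mtr_res", "fwhm"]

BOUNDS_LO = (0.0, 1e-6, 0.0)
BOUNDS_HI = (1.2, 20.0, 1.2)


@dataclass(frozen=True)
class LorentzianFitResult:
    """Fitted reference-line parameters and goodness of fit."""

    a: float  # dip amplitude, dimensionless
    b: float  # width parameter = FWHM, ppm
    c: float  # constant background level
    fit_rss: float
    n_points: int
    at_bound: bool = False

    @property
    def fwhm_ppm(self) -> float:
        return self.b


def lorentzian_ref(dw_ppm: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """Evaluate the reference line ``c - a*(b^2/4)/(b^2/4 + dw^2)``."""
    q = b * b / 4.0
    return c - a * q / (q + np.asarray(dw_ppm) ** 2)


def fit_lorentzian(
    spec: ProcessedZSpectrum,
    exclude_ppm: tuple[float, float] | None = None,
) -> LorentzianFitResult:
    """Least-squares fit of the single Lorentzian reference to a spectrum.

    All valid grid points enter the fit by default; ``exclude_ppm`` can
    carve out a symmetric band (e.g. around a known CEST resonance) but is
    off unless requested.  Initialization is deterministic:
    ``a0 = 1 - min(z)``, ``b0 = 1`` ppm, ``c0 = max(z)``; trust-region
    reflective least squares with bounds a, c in [0, 1.2] and b in
    (0, 20] ppm.
    """
    x = spec.offsets_ppm
    y = spec.z_values
    ok = ~np.isnan(y)
    if exclude_ppm is not None:
        lo, hi = exclude_ppm
        ok &= ~((np.abs(x) >= lo) & (np.abs(x) <= hi))
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("Lorentzian fit needs at least 4 valid grid points")
    a0 = float(np.clip(1.0 - y.min(), 0.0, 1.2))
    c0 = float(np.clip(y.max(), 0.0, 1.2))
    p0 = np.array([a0, 1.0, c0])

    res = least_squares(
        lambda p: lorentzian_ref(x, *p) - y,
        p0,
        bounds=(BOUNDS_LO, BOUNDS_HI),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    if not res.success:
        raise RuntimeError(f"Lorentzian fit did not converge: {res.message}")
    a, b, c = (float(v) for v in res.x)
    at_bound = bool(
        np.any(np.isclose(res.x, BOUNDS_LO, atol=1e-9))
        or np.any(np.isclose(res.x, BOUNDS_HI, atol=1e-9))
    )
    return LorentzianFitResult(
        a=a, b=b, c=c, fit_rss=float(np.sum(res.fun**2)), n_points=len(x), at_bound=at_bound
    )


def mtr_res(
    spec: ProcessedZSpectrum,
    fit: LorentzianFitResult,
    band: tuple[float, float] = DEFAULT_BAND,
) -> MTRasymResult:
    """Residual spectrum ``Zref - Z`` and its band AUC.

    Returned in the same container as the asymmetry analysis so that both
    contrast routes (MTR_asym integral, Lorentzian-difference AUC) are
    interchangeable downstream.
    """
    lo, hi = band
    residual = lorentzian_ref(spec.offsets_ppm, fit.a, fit.b, fit.c) - spec.z_values
    pos = spec.offsets_ppm[spec.offsets_ppm > 0]
    grid = np.unique(np.concatenate([[lo], pos[(pos > lo) & (pos < hi)], [hi]]))
    vals = lorentzian_ref(grid, fit.a, fit.b, fit.c) - spec.value_at(grid)
    if np.any(np.isnan(vals)):
        lo_ok, hi_ok = spec.valid_range()
        raise ValueError(
            f"band {band} ppm extends outside the valid grid ({lo_ok:.3f}, {hi_ok:.3f})"
        )
    auc = float(np.trapezoid(vals, grid))
    return MTRasymResult(
        asym_offsets_ppm=spec.offsets_ppm,
        asym_values=residual,
        band=(lo, hi),
        contrast=auc,
        contrast_mean=auc / (hi - lo),
    )


def fwhm(fit: LorentzianFitResult) -> float:
    """Full width at half maximum of the fitted water line, in ppm.

    For this parameterization the dip ``a*(b^2/4)/(b^2/4+dw^2)`` reaches
    half its peak exactly at ``dw = +/- b/2``, so the FWHM equals ``b``.
    """
    return fit.b
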
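"""Quantitative relaxometry: VFA T1 (Ernst equation) and multi-echo T2.

T1 is estimated from a spoiled gradient-echo series acquired at several
flip angles by fitting the Ernst equation

    S(theta) = M0 sin(theta) (1 - E1) / (1 - E1 cos(theta)),  E1 = exp(-TR/T1)

to the ROI-mean signal.  T2 comes from a mono-exponential fit
``S(TE) = S0 exp(-TE/T2)`` to multi-echo spin-echo signals, done pixel by
pixel; the ROI summary is the mean of the pixel-wise T2 values.  The T1
fit uses a deterministic start from the linearized form (S/sin vs S/tan
regression); the T2 fit is a log-linear ordinary least squares, with an
optional nonlinear refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "VfaSeries",
    "MultiEchoSeries",
    "RelaxFitResult",
    "ernst_signal",
    "ernst_angle_deg",
    "fit_t1_vfa",
    "fit_t2_multiecho",
    "t2_map",
    "roi_t2_mean",
]

T1_BOUNDS_MS = (1.0, 10000.0)


@dataclass
class VfaSeries:
    """Signal per flip angle for the variable-flip-angle T1 experiment."""

    signals: np.ndarray
    flip_angles_deg: tuple[float, ...] = (2.0, 5.0, 8.0, 11.0, 14.0)
    tr_ms: float = 5.8

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if len(self.flip_angles_deg) < 3:
            raise ValueError("need at least 3 flip angles")
        if np.any(np.diff(self.flip_angles_deg) <= 0):
            raise ValueError("flip angles must be strictly increasing")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be > 0")
        if self.signals.shape[0] != len(self.flip_angles_deg):
            raise ValueError("signals length must match flip angles")


@dataclass
class MultiEchoSeries:
    """Signal per echo time for the multi-echo T2 experiment."""

    signals: np.ndarray
    te_ms: tuple[float, ...] = (11.30, 33.89, 56.48, 79.07, 101.66, 124.26)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if len(self.te_ms) < 2:
            raise ValueError("need at least 2 echoes")
        if np.any(np.diff(self.te_ms) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if self.signals.shape[0] != len(self.te_ms):
            raise ValueError("signals length must match echo times")


@dataclass(frozen=True)
class RelaxFitResult:
    """One relaxation-time estimate with amplitude and residual."""

    time_ms: float
    amplitude: float
    fit_rss: float
    valid: bool = True


def ernst_signal(m0: float, t1_ms: float, tr_ms: float, theta_deg: float) -> float:
    """Steady-state spoiled gradient-echo amplitude at one flip angle."""
    if t1_ms <= 0 or tr_ms <= 0:
        raise ValueError("t1_ms and tr_ms must be > 0")
    e1 = np.exp(-tr_ms / t1_ms)
    th = np.deg2rad(theta_deg)
    return m0 * np.sin(th) * (1.0 - e1) / (1.0 - e1 * np.cos(th))


def ernst_angle_deg(t1_ms: float, tr_ms: float) -> float:
    """Flip angle maximizing the Ernst signal: arccos(exp(-TR/T1))."""
    return float(np.rad2deg(np.arccos(np.exp(-tr_ms / t1_ms))))


def fit_t1_vfa(series: VfaSeries) -> RelaxFitResult:
    """Fit (M0, T1) to a VFA series via the Ernst equation.

    Start values come from the classical linearization ``S/sin(theta) =
    E1 * S/tan(theta) + M0 (1 - E1)``; a degenerate slope (outside (0,1))
    marks the series invalid.  The nonlinear refinement is a bounded
    trust-region least squares over (M0, T1).
    """
    th = np.deg2rad(np.asarray(series.flip_angles_deg))
    s = series.signals.astype(float)
    if np.ptp(s) <= 1e-9 * max(abs(s).max(), 1.0):  # flat series carries no T1 information
        return RelaxFitResult(np.nan, np.nan, np.nan, valid=False)
    y = s / np.sin(th)
    x = s / np.tan(th)
    n = len(s)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx <= 0:
        return RelaxFitResult(np.nan, np.nan, np.nan, valid=False)
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    if not 0.0 < slope < 1.0:
        return RelaxFitResult(np.nan, np.nan, np.nan, valid=False)
    t1_0 = float(np.clip(-series.tr_ms / np.log(slope), *T1_BOUNDS_MS))
    m0_0 = float((y.mean() - slope * x.mean()) / (1.0 - slope))
    if not np.isfinite(m0_0) or m0_0 <= 0:
        m0_0 = float(s.max())

    def resid(p: np.ndarray) -> np.ndarray:
        m0, t1 = p
        e1 = np.exp(-series.tr_ms / t1)
        return m0 * np.sin(th) * (1 - e1) / (1 - e1 * np.cos(th)) - s

    res = least_squares(
        resid,
        np.array([m0_0, t1_0]),
        bounds=((0.0, T1_BOUNDS_MS[0]), (np.inf, T1_BOUNDS_MS[1])),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
    )
    m0, t1 = (float(v) for v in res.x)
    at_bound = np.isclose(t1, T1_BOUNDS_MS).any()
    return RelaxFitResult(t1, m0, float(np.sum(res.fun**2)), valid=not at_bound)


def fit_t2_multiecho(series: MultiEchoSeries, refine: bool = False) -> RelaxFitResult:
    """Mono-exponential T2 fit to one multi-echo decay.

    Primary estimator is ordinary least squares on ``ln S`` versus TE,
    which is deterministic and has the two-echo closed form
    ``T2 = (TE2-TE1)/ln(S1/S2)``.  Pixels with any non-positive signal are
    invalid.  ``refine=True`` runs a nonlinear least-squares polish on the
    linear estimate.
    """
    te = np.asarray(series.te_ms, dtype=float)
    s = series.signals.astype(float)
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        return RelaxFitResult(np.nan, np.nan, np.nan, valid=False)
    slope, intercept = np.polyfit(te, np.log(s), 1)
    if slope >= 0:  # no decay: T2 unbounded
        return RelaxFitResult(np.nan, np.nan, np.nan, valid=False)
    t2 = float(-1.0 / slope)
    s0 = float(np.exp(intercept))
    if refine:
        res = least_squares(
            lambda p: p[0] * np.exp(-te / p[1]) - s,
            np.array([s0, t2]),
            bounds=((0.0, 1e-3), (np.inf, np.inf)),
            method="trf",
        )
        s0, t2 = (float(v) for v in res.x)
        rss = float(np.sum(res.fun**2))
    else:
        rss = float(np.sum((s0 * np.exp(-te / t2) - s) ** 2))
    return RelaxFitResult(t2, s0, rss, valid=True)


def t2_map(stack: np.ndarray, te_ms: tuple[float, ...], mask: np.ndarray | None = None) -> np.ndarray:
    """Pixel-wise T2 map (ms) from an echo-time-first image stack.

    ``stack`` has shape ``(n_echoes, ...)``; invalid pixels (non-positive
    signal or no decay) are NaN.
    """
    stack = np.asarray(stack, dtype=float)
    shape = stack.shape[1:]
    out = np.full(shape, np.nan)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    for idx in zip(*np.nonzero(mask)):
        fit = fit_t2_multiecho(MultiEchoSeries(stack[(slice(None), *idx)], te_ms))
        if fit.valid:
            out[idx] = fit.time_ms
    return out


def roi_t2_mean(stack: np.ndarray, te_ms: tuple[float, ...], roi_mask: np.ndarray) -> float:
    """ROI summary: mean of pixel-wise T2 over valid pixels in the ROI."""
    m = t2_map(stack, te_ms, mask=np.asarray(roi_mask, dtype=bool))
    vals = m[np.asarray(roi_mask, dtype=bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI contains no valid T2 fits")
    return float(vals.mean())
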
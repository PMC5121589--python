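"""Gaussian alpha peak over a power-law background.

Each source spectrum P(f) is fit, over a wide 4-14 Hz window, to

    P(f) = A * f**(-B) + C * exp(-(f - f_p)**2 / Delta**2)

by bounded nonlinear least squares with a small multi-start over the peak
frequency. A is the background scale, B the 1/f exponent, C the peak
amplitude, Delta the peak width and f_p the alpha peak frequency — the
quantity carried into the group statistics. The model is scale equivariant:
multiplying a spectrum by k scales A and C by k and leaves B, Delta and f_p
unchanged, so absolute and relative spectra fit identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import ParameterError, StructuralError
from .spectral import PowerSpectrum

__all__ = ["PeakFitResult", "peak_model", "fit_peak", "fit_cohort_peaks"]

#: fitted C below this fraction of the background at f_p counts as "no peak"
PEAK_FLOOR = 0.05

_BOUNDS_LO = np.array([0.0, 0.0, 0.0, 0.2, -np.inf])
_BOUNDS_HI = np.array([np.inf, 4.0, np.inf, 5.0, np.inf])


@dataclass
class PeakFitResult:
    A: float
    B: float
    C: float
    delta: float
    f_p: float
    fit_lo: float
    fit_hi: float
    sse: float
    converged: bool
    peak_present: bool


def peak_model(f: np.ndarray, A: float, B: float, C: float,
               delta: float, f_p: float) -> np.ndarray:
    """Evaluate the Gaussian-peak-plus-power-law model."""
    f = np.asarray(f, dtype=float)
    return A * f ** (-B) + C * np.exp(-((f - f_p) ** 2) / delta**2)


def _loglog_background(f: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Initial (A, B) from a least-squares line in log-log coordinates."""
    pos = y > 0
    if pos.sum() < 2:
        return float(max(y.max(), 1e-12)), 1.0
    lx, ly = np.log(f[pos]), np.log(y[pos])
    b, a = np.polyfit(lx, ly, 1)
    return float(np.exp(a)), float(np.clip(-b, 0.0, 4.0))


def fit_peak(freqs: np.ndarray, power: np.ndarray,
             fit_lo: float = 4.0, fit_hi: float = 14.0) -> PeakFitResult:
    """Fit one spectrum row to the peak-plus-background model over [fit_lo, fit_hi].

    Multi-start: f_p is initialized at the argmax of the background-subtracted
    row within 7-13 Hz plus fixed alternates at 8 and 11 Hz; the best
    sum-of-squares wins, ties broken toward the lower f_p. ``peak_present``
    is False when the fitted amplitude C falls below 5% of the background
    level at f_p.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    mask = (freqs >= fit_lo - 1e-9) & (freqs <= fit_hi + 1e-9)
    f = freqs[mask]
    y = power[mask]
    if f.size < 8:
        raise ParameterError(
            f"need >= 8 frequency bins inside [{fit_lo}, {fit_hi}], got {f.size}"
        )
    if np.any(y < 0):
        raise ParameterError("power values must be non-negative")

    scale = y.max()
    if scale <= 0:
        return PeakFitResult(0.0, 0.0, 0.0, 1.0, fit_lo, fit_lo, fit_hi,
                             0.0, False, False)
    ys = y / scale

    a0, b0 = _loglog_background(f, ys)
    resid0 = ys - a0 * f ** (-b0)
    search = (f >= 7.0) & (f <= 13.0)
    if search.any():
        fp_data = float(f[search][np.argmax(resid0[search])])
    else:
        fp_data = float(f[np.argmax(resid0)])
    c0 = float(max(resid0.max(), 0.05))

    lo = _BOUNDS_LO.copy()
    hi = _BOUNDS_HI.copy()
    lo[4], hi[4] = fit_lo, fit_hi

    def residuals(theta):
        return peak_model(f, *theta) - ys

    best = None
    for fp0 in dict.fromkeys([fp_data, 8.0, 11.0]):  # preserve order, drop dups
        fp0 = float(np.clip(fp0, fit_lo, fit_hi))
        x0 = np.clip([a0, b0, c0, 1.0, fp0], lo, hi)
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        cand = (sse, float(res.x[4]), res)
        if best is None or cand[0] < best[0] - 1e-15 or (
                abs(cand[0] - best[0]) <= 1e-15 and cand[1] < best[1]):
            best = cand
    if best is None:
        return PeakFitResult(float(a0 * scale), b0, float(c0 * scale), 1.0,
                             fp_data, fit_lo, fit_hi, float("inf"),
                             converged=False, peak_present=False)

    sse, _, res = best
    A, B, C, delta, f_p = res.x
    A *= scale
    C *= scale
    background_at_peak = A * f_p ** (-B)
    peak_present = C >= PEAK_FLOOR * background_at_peak and C > 0
    return PeakFitResult(
        A=float(A), B=float(B), C=float(C), delta=float(delta), f_p=float(f_p),
        fit_lo=float(fit_lo), fit_hi=float(fit_hi),
        sse=float(sse * scale**2), converged=bool(res.status > 0),
        peak_present=bool(peak_present),
    )


def fit_cohort_peaks(spectra: list[PowerSpectrum], fit_lo: float = 4.0,
                     fit_hi: float = 14.0) -> np.ndarray:
    """Fit every source row of every subject; return an f_p matrix.

    Returns a (subjects x sources) array with NaN where the fit did not
    converge or no peak was present. All spectra must share one frequency
    axis.
    """
    if not spectra:
        return np.empty((0, 0))
    freqs = spectra[0].freqs
    n_src = spectra[0].n_sources
    out = np.full((len(spectra), n_src), np.nan)
    for i, ps in enumerate(spectra):
        if ps.freqs.shape != freqs.shape or not np.allclose(ps.freqs, freqs):
            raise StructuralError(
                f"spectrum {i} ({ps.subject_id!r}) has a different frequency axis"
            )
        if ps.n_sources != n_src:
            raise StructuralError(
                f"spectrum {i} ({ps.subject_id!r}) has {ps.n_sources} sources, "
                f"expected {n_src}"
            )
        for s in range(n_src):
            fit = fit_peak(freqs, ps.power[s], fit_lo=fit_lo, fit_hi=fit_hi)
            if fit.converged and fit.peak_present:
                out[i, s] = fit.f_p
    return out
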
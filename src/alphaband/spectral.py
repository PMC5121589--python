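"""Multitaper spectra, relative power, IAF detection and band powers.

Spectra are estimated with DPSS (Slepian) multitapers at a configurable
half-bandwidth ("smoothing"), averaged over tapers and epochs, on a fixed
2-45 Hz axis in 0.5 Hz steps by default. Relative power divides each source
row by its own total over the full axis, so band powers are fractions of
total 2-45 Hz power. The individual alpha frequency (IAF) is the most
prominent local maximum of a region-averaged spectrum inside the alpha search
window, and anchors the alpha band at [IAF - 2.5, IAF + 2] Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.signal.windows import dpss

from .cohort import EpochArray
from .errors import ParameterError, StructuralError

__all__ = [
    "PowerSpectrum",
    "BandDefinition",
    "IafEstimate",
    "multitaper_psd",
    "normalize_relative",
    "detect_iaf",
    "alpha_band_from_iaf",
    "band_relative_power",
    "THETA_BAND",
    "BETA_BAND",
]

_EDGE_TOL = 1e-9


@dataclass
class PowerSpectrum:
    """Power as sources x frequencies, with normalization state."""

    freqs: np.ndarray
    power: np.ndarray
    normalized: bool = False
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if self.power.shape[-1] != self.freqs.size:
            raise StructuralError(
                f"power has {self.power.shape[-1]} bins but freqs has {self.freqs.size}"
            )
        if np.any(self.power < -_EDGE_TOL):
            raise ParameterError("power values must be non-negative")

    @property
    def n_sources(self) -> int:
        return self.power.shape[0]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi] Hz inside the 2-45 Hz analysis range."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ParameterError(f"band {self.name!r}: lo {self.lo} must be < hi {self.hi}")
        if self.lo < 2.0 - _EDGE_TOL or self.hi > 45.0 + _EDGE_TOL:
            raise ParameterError(
                f"band {self.name!r} [{self.lo}, {self.hi}] must lie within [2, 45] Hz"
            )


THETA_BAND = BandDefinition("theta", 4.0, 6.9)
BETA_BAND = BandDefinition("beta", 12.0, 30.0)


@dataclass
class IafEstimate:
    """Detected individual alpha frequency."""

    iaf: float
    method: str
    search_range: tuple[float, float]
    fallback: bool = False  # True when no local maximum existed in range


def multitaper_psd(epochs: EpochArray, fmin: float = 2.0, fmax: float = 45.0,
                   fstep: float = 0.5, smoothing: float = 0.5,
                   subject_id: str = "", zero_pad: bool = False) -> PowerSpectrum:
    """DPSS multitaper power spectral density averaged over tapers and epochs.

    The time-bandwidth product is ``epoch_duration * smoothing`` (4-s epochs
    with 0.5 Hz smoothing give NW = 2 and 3 tapers) and the output axis runs
    exactly ``fmin..fmax`` in ``fstep`` steps. With 4-s epochs the native
    resolution is 0.25 Hz and every second bin is retained; if ``fstep`` is
    not a multiple of the native resolution, set ``zero_pad`` to interpolate
    the FFT grid instead.
    """
    n = epochs.n_samples
    fs = epochs.sampling_rate
    duration = n / fs
    nw = duration * smoothing
    n_tapers = int(np.floor(2 * nw - 1))
    if n_tapers < 1:
        raise ParameterError(
            f"smoothing {smoothing} Hz over {duration} s epochs leaves no usable taper "
            f"(time-bandwidth {nw:.3f} < 1)"
        )
    tapers = np.atleast_2d(dpss(n, nw, n_tapers))

    nfft = n
    target = fmin + fstep * np.arange(int(round((fmax - fmin) / fstep)) + 1)
    if target[-1] > fs / 2.0:
        raise ParameterError(f"fmax {fmax} exceeds Nyquist {fs / 2.0}")
    idx = np.round(target * nfft / fs).astype(int)
    if np.max(np.abs(idx * fs / nfft - target)) > 1e-6:
        if not zero_pad:
            raise ParameterError(
                f"fstep {fstep} Hz is not a multiple of the native resolution "
                f"{fs / n:.4g} Hz; set zero_pad=True or change fstep"
            )
        # smallest zero-padded FFT grid whose resolution divides fmin and fstep
        df = np.gcd(int(round(fmin * 1000)), int(round(fstep * 1000))) / 1000.0
        block = int(round(fs / df))
        nfft = block * int(np.ceil(n / block))
        idx = np.round(target * nfft / fs).astype(int)
        if np.max(np.abs(idx * fs / nfft - target)) > 1e-6:
            raise ParameterError(
                f"cannot realize a {fstep} Hz grid from sampling rate {fs} Hz"
            )

    psd = np.zeros((epochs.n_channels, target.size))
    for e in range(epochs.n_epochs):
        x = epochs.data[e]                       # (channels, n)
        xt = x[:, None, :] * tapers[None, :, :]  # (channels, tapers, n)
        spec = np.abs(np.fft.rfft(xt, n=nfft, axis=-1)) ** 2
        psd += spec[..., idx].mean(axis=1)
    psd /= epochs.n_epochs
    # one-sided density scaling (constant factors cancel after normalization)
    psd *= 2.0 / (fs * n)
    return PowerSpectrum(freqs=target, power=psd, normalized=False,
                         subject_id=subject_id)


def normalize_relative(spectrum: PowerSpectrum) -> PowerSpectrum:
    """Divide each source row by its total power over the full axis.

    Idempotent: rows already summing to one are returned unchanged.
    """
    totals = spectrum.power.sum(axis=-1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ParameterError(
            f"cannot normalize zero-power source rows at indices {zero.tolist()}"
        )
    power = spectrum.power / totals[:, None]
    return replace(spectrum, power=power, normalized=True)


def detect_iaf(spectrum: PowerSpectrum, roi_sources: np.ndarray | None = None,
               search_lo: float = 6.0, search_hi: float = 13.0) -> IafEstimate:
    """Find the individual alpha frequency on a region-averaged spectrum.

    The spectrum is averaged over ``roi_sources`` (all sources when None —
    pass a posterior region to emulate occipito-temporal channel selection),
    and the IAF is the frequency of the highest local maximum inside the
    search window. With no local maximum (e.g. a monotone 1/f spectrum) the
    in-range argmax is returned with ``fallback=True``.
    """
    freqs = spectrum.freqs
    if search_lo < freqs[0] - _EDGE_TOL or search_hi > freqs[-1] + _EDGE_TOL:
        raise ParameterError(
            f"search range [{search_lo}, {search_hi}] outside axis "
            f"[{freqs[0]}, {freqs[-1]}]"
        )
    if roi_sources is None:
        roi = np.arange(spectrum.n_sources)
    else:
        roi = np.asarray(roi_sources, dtype=int)
        if roi.size == 0:
            raise ParameterError("roi_sources is empty")
    avg = spectrum.power[roi].mean(axis=0)

    in_range = (freqs >= search_lo - _EDGE_TOL) & (freqs <= search_hi + _EDGE_TOL)
    peaks, _ = signal.find_peaks(avg)
    peaks = peaks[in_range[peaks]]
    method = "source-average-peak" if spectrum.power.shape[0] > 1 else "sensor-average-peak"
    if peaks.size:
        best = peaks[np.argmax(avg[peaks])]
        return IafEstimate(iaf=float(freqs[best]), method=method,
                           search_range=(search_lo, search_hi), fallback=False)
    sub = np.flatnonzero(in_range)
    best = sub[np.argmax(avg[sub])]
    return IafEstimate(iaf=float(freqs[best]), method=method,
                       search_range=(search_lo, search_hi), fallback=True)


def alpha_band_from_iaf(iaf: float) -> BandDefinition:
    """Anchor the alpha band at [IAF - 2.5, IAF + 2] Hz."""
    if not 4.0 < iaf < 14.0:
        raise ParameterError(f"IAF must lie in (4, 14) Hz, got {iaf}")
    lo, hi = iaf - 2.5, iaf + 2.0
    if lo < 2.0 or hi > 45.0:
        raise ParameterError(
            f"anchored alpha band [{lo:.2f}, {hi:.2f}] falls outside [2, 45] Hz"
        )
    return BandDefinition("alpha", round(lo, 10), round(hi, 10))


def band_relative_power(spectrum: PowerSpectrum, band: BandDefinition) -> np.ndarray:
    """Per-source band power: sum of relative power over bins in [lo, hi].

    Band edges are inclusive; bins are point frequencies on the analysis
    grid. Requires a normalized spectrum so the result is a fraction of total
    2-45 Hz power.
    """
    if not spectrum.normalized:
        raise ParameterError("band_relative_power requires a normalized spectrum")
    freqs = spectrum.freqs
    if band.lo < freqs[0] - _EDGE_TOL or band.hi > freqs[-1] + _EDGE_TOL:
        raise ParameterError(
            f"band [{band.lo}, {band.hi}] outside spectrum axis [{freqs[0]}, {freqs[-1]}]"
        )
    mask = (freqs >= band.lo - _EDGE_TOL) & (freqs <= band.hi + _EDGE_TOL)
    return spectrum.power[:, mask].sum(axis=-1)
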
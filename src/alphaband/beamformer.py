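"""Toy forward model and LCMV beamformer.

The forward model maps source activity to a synthetic sensor array through a
random, spatially smoothed gain matrix (a stand-in geometry: realistic BEM
leadfields are out of scope). The inverse step is a scalar linearly
constrained minimum variance (LCMV) beamformer in the Van Veen formulation:
for each source with leadfield column l and regularized sensor covariance C,

    w = (l' C^-1 l)^-1 l' C^-1

which has unit gain at the target source and minimum output variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .cohort import EpochArray, SourceGrid
from .errors import NumericalError, ParameterError, StructuralError

__all__ = [
    "Leadfield",
    "SpatialFilter",
    "make_leadfield",
    "bandpass_epochs",
    "epoch_covariance",
    "lcmv_filter",
    "reconstruct_sources",
]


@dataclass
class Leadfield:
    """Fixed-orientation gain matrix, sensors x sources."""

    gain: np.ndarray

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise StructuralError(f"gain must be 2-D, got shape {self.gain.shape}")
        if not np.all(np.isfinite(self.gain)):
            raise NumericalError("leadfield gain contains non-finite entries")
        norms = np.linalg.norm(self.gain, axis=0)
        if np.any(norms == 0):
            raise NumericalError(
                f"leadfield has all-zero columns at sources {np.flatnonzero(norms == 0)}"
            )

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class SpatialFilter:
    """LCMV weights, sources x sensors, unit gain at each target source."""

    weights: np.ndarray
    regularization: float

    @property
    def n_sources(self) -> int:
        return self.weights.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.weights.shape[1]


def make_leadfield(grid: SourceGrid, n_sensors: int, seed: int = 0,
                   smoothness_mm: float = 20.0) -> Leadfield:
    """Draw a synthetic leadfield with smooth spatial structure.

    Sensor patterns are i.i.d. Gaussian per source, then mixed across sources
    with a Gaussian kernel over grid distance so neighboring sources see
    correlated topographies (as physical leadfields do), and finally column
    normalized.
    """
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_sensors, grid.n_sources))
    diff = grid.positions[:, None, :] - grid.positions[None, :, :]
    d2 = (diff**2).sum(-1)
    kernel = np.exp(-d2 / (2.0 * smoothness_mm**2))
    gain = raw @ kernel
    gain /= np.linalg.norm(gain, axis=0, keepdims=True)
    return Leadfield(gain=gain)


def bandpass_epochs(epochs: EpochArray, lo: float, hi: float,
                    pad_seconds: float = 2.0, order: int = 4) -> EpochArray:
    """Zero-phase band-pass filter of every epoch.

    Uses a forward-backward Butterworth filter. Each epoch is mirror-padded by
    ``pad_seconds`` on both sides before filtering to suppress edge
    transients (synthetic epochs have no real adjacent signal to pad with).
    """
    fs = epochs.sampling_rate
    nyq = fs / 2.0
    if hi >= nyq:
        raise ParameterError(f"upper edge {hi} Hz must be below Nyquist {nyq} Hz")
    if not 0 < lo < hi:
        raise ParameterError(f"band edges must satisfy 0 < lo < hi, got ({lo}, {hi})")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    pad = int(round(pad_seconds * fs))
    pad = min(pad, epochs.n_samples - 1)
    data = epochs.data
    if pad > 0:
        data = np.pad(data, ((0, 0), (0, 0), (pad, pad)), mode="reflect")
    out = signal.sosfiltfilt(sos, data, axis=-1)
    if pad > 0:
        out = out[..., pad:-pad]
    return EpochArray(data=np.ascontiguousarray(out),
                      sampling_rate=fs, space=epochs.space)


def epoch_covariance(epochs: EpochArray) -> np.ndarray:
    """Epoch-averaged sensor covariance.

    Each epoch contributes its own sample covariance (per-epoch mean removed);
    the result is the average across epochs, symmetric PSD by construction.
    """
    if epochs.n_epochs < 2:
        raise ParameterError(f"need >= 2 epochs, got {epochs.n_epochs}")
    if epochs.n_samples < epochs.n_channels:
        warnings.warn(
            "fewer samples than sensors per epoch: covariance is rank deficient, "
            "regularization mandatory",
            stacklevel=2,
        )
    x = epochs.data - epochs.data.mean(axis=-1, keepdims=True)
    cov = np.einsum("ecs,eds->cd", x, x) / (epochs.n_epochs * (epochs.n_samples - 1))
    return 0.5 * (cov + cov.T)


def lcmv_filter(leadfield: Leadfield, cov: np.ndarray, reg: float = 0.05) -> SpatialFilter:
    """Build the LCMV spatial filter from a leadfield and sensor covariance.

    ``reg`` is the diagonal loading fraction: ``reg * trace(C) / n_sensors``
    is added to the covariance diagonal before inversion.
    """
    cov = np.asarray(cov, dtype=float)
    m = leadfield.n_sensors
    if cov.shape != (m, m):
        raise StructuralError(
            f"covariance shape {cov.shape} does not match {m} sensors"
        )
    loading = reg * np.trace(cov) / m
    c_reg = cov + loading * np.eye(m)
    try:
        c_inv = np.linalg.inv(c_reg)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "regularized covariance is singular; raise reg above "
            f"{reg}"
        ) from exc
    g = leadfield.gain
    cig = c_inv @ g                       # (m, n_sources)
    denom = np.einsum("ms,ms->s", g, cig)  # l' C^-1 l per source
    if np.any(denom <= 0):
        raise NumericalError("non-positive beamformer denominator; raise reg")
    weights = (cig / denom).T             # (n_sources, m)
    return SpatialFilter(weights=weights, regularization=float(reg))


def reconstruct_sources(filt: SpatialFilter, epochs: EpochArray) -> EpochArray:
    """Apply the spatial filter to sensor epochs, yielding source epochs."""
    if epochs.n_channels != filt.n_sensors:
        raise StructuralError(
            f"epochs have {epochs.n_channels} channels but filter expects "
            f"{filt.n_sensors} sensors"
        )
    out = np.einsum("sm,emt->est", filt.weights, epochs.data)
    return EpochArray(data=out, sampling_rate=epochs.sampling_rate, space="source")
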
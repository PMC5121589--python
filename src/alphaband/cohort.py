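"""Synthetic resting-state cohort generator.

Builds a three-group elderly cohort (no SCD / SCD / MCI) with the statistical
structure the downstream spectral analysis assumes: per-subject alpha
oscillations at a latent individual alpha frequency (IAF) riding on a 1/f
background, demographics, neuropsychological scores that are linear in the
latent spectral truths, and ICV-normalized hippocampal volumes.

The generator is the test bed for the whole pipeline: every latent quantity
(IAF, alpha relative power, score coefficients) is recorded on the subject so
recovery can be checked end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NumericalError, ParameterError

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "EpochArray",
    "SourceGrid",
    "CohortDataset",
    "DEFAULT_SCORE_COEFFICIENTS",
    "build_source_grid",
    "generate_cohort",
    "generate_epochs",
]

GROUPS = ("noSCD", "SCD", "MCI")

#: Score-generator coefficients per criterion:
#: (intercept, beta_power, beta_peak, noise_sd).
#: Nonzero slopes mark criteria genuinely driven by alpha relative power
#: (5 criteria) or alpha peak frequency (11 criteria); intercepts place the
#: criterion mean at a realistic level for predictors near (0.35, 9.4 Hz).
DEFAULT_SCORE_COEFFICIENTS: dict[str, tuple[float, float, float, float]] = {
    "MMSE": (23.93, 0.0, 0.47, 1.2),
    "Direct Digit": (8.05, 0.0, 0.0, 2.0),
    "Inverse Digit": (2.79, 7.28, 0.0, 1.7),
    "Immediate Recall": (-9.51, 0.0, 4.29, 11.0),
    "Delayed Recall": (-18.81, 0.0, 3.81, 9.0),
    "Rule Shift Cards": (-2.37, 4.10, 0.42, 0.9),
    "FAS-phonemic": (11.65, 0.0, 0.0, 4.5),
    "FAS-semantic": (5.65, 0.0, 1.09, 3.5),
    "TMTA (hits)": (21.84, 0.0, 0.22, 0.6),
    "TMTA (time)": (143.4, 0.0, -8.72, 22.0),
    "TMTB (hits)": (-3.99, 18.56, 2.02, 3.8),
    "TMTB (time)": (265.1, -326.4, 0.0, 70.0),
    "Ideomotor Praxis": (4.61, 0.0, 0.30, 0.85),
    "BNT": (16.35, 28.86, 2.41, 6.5),
    "Hippocampal Volume": (2.54e-3, 0.0, 2.2e-4, 5e-4),
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions at desk scale: group sizes
    39/41/51 with group IAF means 9.8/9.6/9.0 Hz (SD 0.9), 4-second epochs,
    and a cubic source grid. Sampling rate, epoch count and source count are
    reduced from recording scale (1000 Hz, ~45 epochs, 2459 sources) to keep
    simulation tractable; all are overridable.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"noSCD": 39, "SCD": 41, "MCI": 51}
    )
    iaf_mean: dict[str, float] = field(
        default_factory=lambda: {"noSCD": 9.8, "SCD": 9.6, "MCI": 9.0}
    )
    iaf_sd: dict[str, float] = field(
        default_factory=lambda: {"noSCD": 0.9, "SCD": 0.9, "MCI": 0.9}
    )
    alpha_relpower_mean: dict[str, float] = field(
        default_factory=lambda: {"noSCD": 0.40, "SCD": 0.32, "MCI": 0.30}
    )
    alpha_relpower_sd: float = 0.08
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"noSCD": 70.4, "SCD": 71.6, "MCI": 73.0}
    )
    age_sd: float = 4.0
    background_exponent: float = 1.0
    background_scale: float = 1.0  # 0 disables the 1/f floor (pure oscillation)
    epoch_count: int = 20
    epoch_duration: float = 4.0
    sampling_rate: float = 250.0
    n_per_axis: int = 5
    grid_spacing: float = 10.0  # mm
    score_coefficients: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_COEFFICIENTS)
    )
    seed: int = 0

    @property
    def n_sources(self) -> int:
        return int(self.n_per_axis) ** 3

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_duration * self.sampling_rate))

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ConfigurationError(f"group_sizes[{g!r}] must be >= 1, got {n}")
        for g in self.group_sizes:
            for name in ("iaf_mean", "iaf_sd", "alpha_relpower_mean", "age_mean"):
                if g not in getattr(self, name):
                    raise ConfigurationError(f"{name} missing entry for group {g!r}")
        for g, mu in self.iaf_mean.items():
            if not 4.0 < mu < 14.0:
                raise ConfigurationError(f"iaf_mean[{g!r}] must lie in (4, 14) Hz, got {mu}")
        for g, r in self.alpha_relpower_mean.items():
            if not 0.0 < r < 1.0:
                raise ConfigurationError(
                    f"alpha_relpower_mean[{g!r}] must lie in (0, 1), got {r}"
                )
        n_samp = self.epoch_duration * self.sampling_rate
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ConfigurationError(
                "epoch_duration * sampling_rate must be an integer number of samples, "
                f"got {n_samp}"
            )
        if self.epoch_count < 1:
            raise ConfigurationError(f"epoch_count must be >= 1, got {self.epoch_count}")
        if self.n_per_axis < 1:
            raise ConfigurationError(f"n_per_axis must be >= 1, got {self.n_per_axis}")
        for crit, coefs in self.score_coefficients.items():
            if len(coefs) != 4:
                raise ConfigurationError(
                    f"score_coefficients[{crit!r}] must be "
                    "(intercept, beta_power, beta_peak, noise_sd)"
                )


@dataclass
class EpochArray:
    """Epoched time series, ``data`` shaped (epochs, channels-or-sources, samples)."""

    data: np.ndarray
    sampling_rate: float
    space: str = "source"  # "sensor" or "source"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ParameterError(
                f"EpochArray.data must be 3-D (epochs, channels, samples), got {self.data.shape}"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class SourceGrid:
    """Regular cubic source grid with a distance-threshold adjacency."""

    positions: np.ndarray  # (n_sources, 3), mm
    spacing: float
    adjacency: np.ndarray  # boolean (n_sources, n_sources), empty diagonal

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    def posterior_roi(self, fraction: float = 1 / 3, axis: int = 1) -> np.ndarray:
        """Indices of the posterior ``fraction`` of sources along one axis.

        Stands in for the occipito-temporal sensor selection used when
        identifying the individual alpha frequency.
        """
        coord = self.positions[:, axis]
        cutoff = np.quantile(coord, fraction)
        roi = np.flatnonzero(coord <= cutoff + 1e-9)
        return roi


@dataclass
class SubjectRecord:
    """One simulated participant with latent generator truths."""

    subject_id: str
    group: str
    age: float
    iaf_true: float
    alpha_relpower_true: float
    scores: dict[str, float]
    hippocampal_volume: float
    signal_seed: int
    epochs: EpochArray | None = None


@dataclass
class CohortDataset:
    """A generated cohort: subject records plus the shared source grid."""

    subjects: list[SubjectRecord]
    grid: SourceGrid
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects])

    def to_frame(self) -> pd.DataFrame:
        """Tabulate demographics, latent truths and scores, one row per subject."""
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "iaf_true": s.iaf_true,
                "alpha_relpower_true": s.alpha_relpower_true,
                "hippocampal_volume": s.hippocampal_volume,
            }
            row.update(s.scores)
            rows.append(row)
        return pd.DataFrame(rows)


def build_source_grid(
    n_per_axis: int | tuple[int, int, int],
    spacing: float,
    neighbor_radius: float | None = None,
) -> SourceGrid:
    """Build a cubic lattice of sources with distance-threshold adjacency.

    Parameters
    ----------
    n_per_axis
        Number of lattice nodes per axis (int for a cube, or a 3-tuple).
    spacing
        Lattice constant in mm (1-cm grids are the conventional choice).
    neighbor_radius
        Two sources are adjacent iff their Euclidean distance is at most this
        radius. Defaults to ``1.01 * spacing`` (face adjacency).
    """
    if isinstance(n_per_axis, (int, np.integer)):
        dims = (int(n_per_axis),) * 3
    else:
        dims = tuple(int(d) for d in n_per_axis)
        if len(dims) != 3:
            raise ParameterError(f"n_per_axis must be an int or 3-tuple, got {n_per_axis!r}")
    if max(dims) < 2 and np.prod(dims) < 2:
        raise ParameterError("grid needs at least 2 sources")
    if neighbor_radius is None:
        neighbor_radius = 1.01 * spacing
    if neighbor_radius < spacing:
        warnings.warn(
            f"neighbor_radius {neighbor_radius} < spacing {spacing}: grid has no edges",
            stacklevel=2,
        )
    axes = [np.arange(d) * spacing for d in dims]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    positions = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]).astype(float)
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    adjacency = (dist <= neighbor_radius + 1e-12) & (dist > 0)
    return SourceGrid(positions=positions, spacing=float(spacing), adjacency=adjacency)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """Rejection-sample one draw of N(mean, sd) truncated to (lo, hi)."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise NumericalError(  # pragma: no cover
        f"truncated-normal rejection failed: N({mean}, {sd}) on ({lo}, {hi})"
    )


def _noise_shape(freqs: np.ndarray, exponent: float) -> np.ndarray:
    """Amplitude shaping f^(-exponent/2) with the DC bin zeroed.

    Frequencies below 1 Hz are clamped to the 1-Hz amplitude so the synthetic
    floor does not blow up at the low edge; content below the 2-Hz analysis
    band is irrelevant downstream.
    """
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = np.maximum(freqs[nz], 1.0) ** (-exponent / 2.0)
    return amp


def _alpha_amplitude(target_rel: float, noise_fraction_alpha: float,
                     noise_scale: float) -> float:
    """Sinusoid amplitude achieving a target alpha relative power.

    With in-band (2-45 Hz) noise variance ``noise_scale**2`` of which a
    fraction ``q`` falls in the alpha band, relative alpha power of the
    sinusoid-plus-noise mixture is r = (a^2/2 + q P) / (a^2/2 + P); solving
    for the sinusoid power a^2/2 gives P (r - q) / (1 - r).
    """
    if noise_scale == 0:
        return 1.0
    p_noise = noise_scale**2
    q = noise_fraction_alpha
    r = target_rel
    sin_power = p_noise * max(r - q, 0.0) / max(1.0 - r, 1e-6)
    return float(np.sqrt(2.0 * sin_power))


def generate_epochs(config: CohortConfig, subject: SubjectRecord,
                    n_sources: int | None = None) -> EpochArray:
    """Synthesize source-space epochs for one subject.

    Each source carries a sinusoid at the subject's latent IAF (uniform random
    phase per epoch and source) over an independent 1/f^chi noise floor whose
    in-band variance is unity, with the sinusoid amplitude calibrated so the
    expected alpha relative power over 2-45 Hz matches the subject's latent
    target. Fully determined by the subject's ``signal_seed``.
    """
    rng = np.random.default_rng(subject.signal_seed)
    n_src = config.n_sources if n_sources is None else int(n_sources)
    n_ep = config.epoch_count
    n = config.n_samples
    fs = config.sampling_rate
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = _noise_shape(freqs, config.background_exponent)

    band = (freqs >= 2.0) & (freqs <= 45.0)
    lo, hi = subject.iaf_true - 2.5, subject.iaf_true + 2.0
    alpha = (freqs >= lo) & (freqs <= hi)
    band_power = (amp[band] ** 2).sum()
    q = (amp[band & alpha] ** 2).sum() / band_power if band_power > 0 else 0.0
    # scale so that expected in-band variance of the noise equals background_scale^2
    if band_power > 0 and config.background_scale > 0:
        amp = amp * config.background_scale * np.sqrt(n**2 / (2.0 * band_power))
    else:
        amp = amp * 0.0
    a_sin = _alpha_amplitude(subject.alpha_relpower_true, q, config.background_scale)

    t = np.arange(n) / fs
    data = np.empty((n_ep, n_src, n), dtype=float)
    for e in range(n_ep):
        z = (rng.standard_normal((n_src, freqs.size))
             + 1j * rng.standard_normal((n_src, freqs.size))) / np.sqrt(2.0)
        noise = np.fft.irfft(z * amp, n=n, axis=-1)
        phase = rng.uniform(0.0, 2.0 * np.pi, size=(n_src, 1))
        data[e] = noise + a_sin * np.sin(2.0 * np.pi * subject.iaf_true * t + phase)
    return EpochArray(data=data, sampling_rate=fs, space="source")


def generate_cohort(config: CohortConfig | None = None,
                    with_signals: bool = False) -> CohortDataset:
    """Generate a full cohort from a configuration.

    Per group, subject IAFs are drawn from the configured normal law truncated
    to (4, 14) Hz; alpha relative-power targets from a normal law truncated to
    (0.05, 0.95); ages from a normal law. Scores follow
    ``intercept + beta_power * alpha_relpower_true + beta_peak * iaf_true +
    noise``. Identical config and seed give bitwise-identical output.

    Parameters
    ----------
    config
        Cohort parameters; defaults to the study conditions at desk scale.
    with_signals
        If True, synthesize and attach source-space epochs eagerly. Leave
        False for statistics-only cohorts or to generate per subject lazily
        via :func:`generate_epochs`.
    """
    config = CohortConfig() if config is None else config
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = build_source_grid(config.n_per_axis, config.grid_spacing)

    subjects: list[SubjectRecord] = []
    idx = 0
    for group, n_sub in config.group_sizes.items():
        for _ in range(n_sub):
            idx += 1
            age = rng.normal(config.age_mean[group], config.age_sd)
            iaf = _truncated_normal(rng, config.iaf_mean[group],
                                    config.iaf_sd[group], 4.0, 14.0)
            relp = _truncated_normal(rng, config.alpha_relpower_mean[group],
                                     config.alpha_relpower_sd, 0.05, 0.95)
            signal_seed = int(rng.integers(2**31))
            scores = {}
            for crit, (b0, b_pow, b_peak, noise_sd) in config.score_coefficients.items():
                eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                scores[crit] = b0 + b_pow * relp + b_peak * iaf + eps
            hippo = scores.get("Hippocampal Volume", 5e-3)
            hippo = max(hippo, 1e-6)  # ICV-normalized volume is strictly positive
            if "Hippocampal Volume" in scores:
                scores["Hippocampal Volume"] = hippo
            subjects.append(SubjectRecord(
                subject_id=f"sub-{idx:03d}",
                group=group,
                age=float(age),
                iaf_true=iaf,
                alpha_relpower_true=relp,
                scores=scores,
                hippocampal_volume=hippo,
                signal_seed=signal_seed,
            ))
    cohort = CohortDataset(subjects=subjects, grid=grid, config=config)
    if with_signals:
        for s in cohort.subjects:
            s.epochs = generate_epochs(config, s)
    return cohort


def scaled_config(base: CohortConfig | None = None, **overrides) -> CohortConfig:
    """Convenience: copy a config with field overrides."""
    base = CohortConfig() if base is None else base
    return replace(base, **overrides)
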
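# Methods

This note documents the models, parameter choices and numerical decisions
behind `alphaband`, and what the synthetic test bed does and does not
establish about real recordings.

## Synthetic cohort model

The generator emulates a three-group resting-state MEG study of the early
Alzheimer's continuum. Per subject it draws:

- **IAF** from a group-specific normal law truncated to (4, 14) Hz. Defaults:
  means 9.8 / 9.6 / 9.0 Hz for no SCD / SCD / MCI, SD 0.9 Hz.
- **Alpha relative power target** from a normal law truncated to
  (0.05, 0.95). Defaults 0.40 / 0.32 / 0.30 (SD 0.08): the no-SCD group sits
  at a typical eyes-closed resting level and both impaired groups share a
  comparable reduction, which is the qualitative pattern the pipeline is
  meant to resolve. These fractions are design choices — the underlying
  study type reports maps, not scalar group power values.
- **Age** from a normal law (means 70.4 / 71.6 / 73.0 y, SD 4 y).
- **Scores** for 14 neuropsychological criteria plus ICV-normalized
  hippocampal volume as `β₀ + β₁·power_true + β₂·IAF_true + ε`. Eleven
  criteria carry a nonzero peak-frequency slope and five a nonzero power
  slope, matching the empirical significance pattern such batteries report;
  intercepts are set so criterion means land at realistic levels for
  predictors near (0.35, 9.4 Hz), and noise SDs approximate published
  cohort SDs.

**Signals.** Each source's epoch is a sinusoid at the subject's IAF with
uniform random phase (per epoch and source) over an independent 1/f^χ noise
floor (χ = 1 by default), synthesized by shaping white-noise Fourier
coefficients and scaled so the expected 2–45 Hz noise variance is 1. The
sinusoid amplitude solves r = (a²/2 + qP)/(a²/2 + P) for the target relative
power r, where q is the noise fraction inside the subject's alpha band. The
calibration is analytic and approximate: band-pass filtering removes part of
the low-frequency noise, so measured relative power runs slightly above the
target. This bias is common to all groups and leaves orderings — the
quantity the statistics consume — intact; the monotonicity test pins it
down.

**What the generator does not emulate:** anatomically placed sources,
sensor noise and artifacts, non-sinusoidal or amplitude-modulated alpha,
between-source power gradients, and any dependence of scores on age.
Passing tests therefore demonstrate correctness of the estimators and the
inference machinery under the assumed generative model, not clinical
validity on real recordings.

**Scale defaults.** 20 four-second epochs per subject at 250 Hz over a
5×5×5 grid with 10 mm spacing. These desk-scale defaults keep a full cohort
simulation in the minutes range; recording-scale values (1000 Hz, ~45
epochs, thousands of sources) are plain config overrides. Tests and the
acceptance script mostly use 2×2×2 grids (8 sources), which is enough
because sources are statistically exchangeable in the generator.

## Forward model and beamformer

The synthetic leadfield draws i.i.d. Gaussian sensor patterns per source and
mixes them across sources with a Gaussian kernel over grid distance
(smoothness 20 mm), then normalizes columns — giving the smooth spatial
correlation structure physical leadfields have without any head geometry.
Orientation is fixed (scalar beamformer). The LCMV weights follow the Van
Veen formulation with diagonal loading `reg·trace(C)/m` (default reg =
0.05); unit gain at the target source holds to machine precision and is
asserted at 1e-6. Band-pass filtering is a zero-phase (forward–backward)
order-4 Butterworth; epochs are mirror-padded by 2 s before filtering since
synthetic epochs have no adjacent real signal. The measured stop-band
attenuation one octave outside 2–45 Hz exceeds 20 dB.

## Spectral estimation

Multitaper PSD with DPSS tapers; the time-bandwidth product is epoch
duration × smoothing, so 4-s epochs at the default 0.5 Hz smoothing give
NW = 2 and 3 tapers. The 2–45 Hz axis in 0.5 Hz steps is realized by
computing at the native resolution (0.25 Hz for 4-s epochs) and retaining
every second bin; `zero_pad=True` handles epoch lengths whose native grid
does not divide the requested step. Relative power divides each source row
by its own total over the full axis, making rows sum to one.

IAF detection is automated: the highest local maximum of the ROI-averaged
spectrum within a [6, 13] Hz search window (the window is a package choice;
manual identification is the field's tradition). If no local maximum exists
the in-range argmax is returned with a fallback flag. The default ROI is the
posterior third of the grid along one axis, standing in for
occipito-temporal channel selection. The alpha band is anchored at
[IAF − 2.5, IAF + 2] Hz from the *sample-average* IAF rounded to one
decimal, so a 9.4 Hz sample yields [6.9, 11.4] Hz for everyone; band edges
are inclusive and bins are point frequencies.

## Peak model

`P(f) = A·f^(−B) + C·exp(−(f − f_p)²/Δ²)` over 4–14 Hz, fit by bounded
trust-region least squares (B ∈ [0, 4], Δ ∈ [0.2, 5] Hz, f_p in the fit
range, A, C ≥ 0). The Δ² (not 2Δ²) denominator convention is adopted;
recovery tests are internally consistent under either convention. Rows are
max-normalized before fitting and A, C rescaled afterwards, which makes the
implementation exactly scale-equivariant. Multi-start: f_p begins at the
argmax of the row minus a log-log background line within 7–13 Hz, plus fixed
alternates at 8 and 11 Hz; best SSE wins, ties to the lower f_p. A fit is
flagged "no peak" when C < 5% of the background level at f_p — a package
rejection rule; entries so flagged propagate as missing. Noiseless model
curves are recovered to 1e-3 and the median |f_p| error at 1% noise stays
within 0.1 Hz.

## Group statistics

**ANCOVA.** value ~ group + age by OLS, partial F test for the group
factor, Tukey HSD on age-adjusted values (y − b_age·(age − mean age)) when
the factor is significant at 0.05. Type-I error is calibrated to 5% ± 2%
in simulation.

**Cluster-based permutation tests.** Per source, the signed t of the group
coefficient from the group+age model; sources with parametric two-sided
p < cluster_alpha (default 0.05 — cluster-forming thresholds are always a
choice, exposed in config) form clusters under grid adjacency, positive and
negative excursions separately; cluster mass is the summed F (= t²). The
null is the maximum cluster mass over both signs across permutations, and
cluster p = (1 + #{null ≥ mass})/(n_perm + 1), with n_perm = 2000 by
default. With complete maps the covariate is respected via Freedman–Lane:
residuals of the age-only model are permuted and the age fit re-added. With
per-source missing entries (no-peak fits) residual rows cannot be permuted
across differing subject subsets, so the test falls back to permuting group
labels with age kept attached, computing per-source statistics on each
missingness pattern; sources observed in fewer than 80% of subjects are
excluded beforehand. An exact mode enumerates all group-label assignments
(covariate-free, small n) and serves as the oracle for the Monte-Carlo
path. Family-wise error under a simulated null is ≤ 0.07 and planted
8-source effects are recovered with Jaccard ≥ 0.5.

**Regression battery.** Per criterion, OLS of the score on subject-average
alpha relative power and peak frequency entered together; BH FDR at q = 0.1
over the pooled family of all slope p-values (2 × 15 = 30 tests). Pooling
both predictors into one family is the package default because one stated
correction suggests one family; a per-predictor option exists. Missing f_p
entries are averaged out per subject before regression (mean over
non-missing sources).

## Determinism and problem sizes

Every stochastic step takes an explicit seed: the cohort seed drives one
generator stream that also assigns per-subject signal seeds (< 2³¹), and
permutation tests seed their own generators, so identical configs give
bitwise-identical tables. Calibration suites use reduced sizes chosen as
the package's own test design: 200 null datasets at 500 permutations and
64 sources for the cluster-test calibration, 500 simulated cohorts for FDR
calibration, 8-source grids for full-pipeline recovery runs.

## Known limitations

- The sinusoid-plus-1/f generator has no peak-width variability; fitted Δ
  often sits at its lower bound on synthetic lines.
- Relative-power targeting is biased slightly upward (band-edge filtering);
  use the monotone ordering, not the absolute level.
- The label-permutation fallback under missing data is slightly less
  powerful than Freedman–Lane and treats age as exchangeable with respect
  to group under the null.
- The synthetic leadfield has no null space structure of real MEG (no
  radial-source insensitivity); beamformer performance on it is optimistic.
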
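# alphaband

Source-space alpha-band spectral statistics for MEG/EEG resting-state
cohorts, built around the questions asked in early Alzheimer's-continuum
research: do elders with subjective cognitive decline (SCD) or mild
cognitive impairment (MCI) show reduced alpha relative power or a slowed
alpha peak compared with unimpaired elders, and do those spectral parameters
predict cognition?

Because raw clinical MEG is rarely shareable, the package ships a synthetic
cohort generator that reproduces the statistical structure of such a study —
three groups (no SCD / SCD / MCI, n = 39/41/51 by default) with
group-specific individual alpha frequencies (IAF; 9.8/9.6/9.0 ± 0.9 Hz),
alpha oscillations over a 1/f background, ages, neuropsychological scores and
ICV-normalized hippocampal volumes — so the entire analysis chain is testable
end to end with known ground truth.

## What the pipeline computes

1. **Forward/inverse (optional).** Synthetic leadfield plus a scalar LCMV
   beamformer, `w = (lᵀC⁻¹l)⁻¹ lᵀC⁻¹`, built per subject from the
   epoch-averaged sensor covariance of 2–45 Hz band-passed 4-s epochs.
2. **Spectra.** DPSS multitaper PSD on 2–45 Hz in 0.5 Hz steps with 0.5 Hz
   smoothing (NW = 2, 3 tapers for 4-s epochs), normalized to relative power
   so each source spectrum sums to 1.
3. **IAF and bands.** The IAF is the most prominent spectral peak of a
   posterior-region average; the alpha band is anchored at
   [IAF − 2.5, IAF + 2] Hz (a 9.4 Hz sample average gives [6.9, 11.4] Hz),
   with theta [4, 6.9] and beta [12, 30] Hz as secondary bands.
4. **Peak model.** Per source, `P(f) = A·f^(−B) + C·exp(−(f − f_p)²/Δ²)` is
   fit over 4–14 Hz by bounded nonlinear least squares; `f_p` is the alpha
   peak frequency.
5. **Statistics.** Age-covaried ANCOVA + Tukey HSD for scalar measures;
   cluster-based permutation tests (Freedman–Lane scheme, 2000 Monte-Carlo
   permutations, α = 0.05) over the source grid for alpha power and `f_p`
   contrasts; and per criterion the two-predictor regression
   `y = β₀ + β₁·power + β₂·peak + ε` with Benjamini–Hochberg FDR at q = 0.1.

## Worked example

```python
from alphaband import CohortConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    cohort=CohortConfig(n_per_axis=2, epoch_count=6, seed=1),
    n_perm=200, seed=1,
)
report = run_pipeline(config)
print(f"sample-average IAF: {report.sample_iaf} Hz")
print(f"alpha band: {report.alpha_band}")
print(report.group_summary[["group", "n", "IAF mean", "IAF sd"]])
```

prints

```
sample-average IAF: 9.5 Hz
alpha band: (7.0, 11.5)
   group   n  IAF mean    IAF sd
0  noSCD  39  9.794872  0.863880
1    SCD  41  9.707317  1.106659
2    MCI  51  8.990196  0.897163
```

The detected group-mean IAFs track the generator's targets (9.8/9.6/9.0 Hz);
the sample-average IAF anchors the alpha band used for the band-power maps;
`report.contrasts` holds the cluster tables per contrast and
`report.regression` the battery with FDR flags. The same run is available
from the shell:

```bash
alphaband run-all --out out/ --seed 1 --n-per-axis 2 --epochs 6 --n-perm 200
```

with `simulate`, `reconstruct`, `spectra`, `fit-peaks`, `cluster-test`,
`regress` and `report` as stage-wise subcommands over the same artifact
directory.

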
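"""Multitaper spectra, relative power, IAF detection and band powers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alphaband import (BandDefinition, CohortConfig, EpochArray, PowerSpectrum,
                       alpha_band_from_iaf, band_relative_power, detect_iaf,
                       generate_cohort, generate_epochs, multitaper_psd,
                       normalize_relative)
from alphaband.errors import ParameterError

FS = 250.0
FREQS = 2.0 + 0.5 * np.arange(87)  # the standard 2-45 Hz half-Hz axis


def _epochs(data):
    return EpochArray(np.asarray(data, dtype=float), FS, "source")


def _gaussian_spectrum(center, width=1.0, amp=1.0):
    power = amp * np.exp(-((FREQS - center) ** 2) / width**2) + 1e-6
    return normalize_relative(PowerSpectrum(FREQS, power[None, :]))


class TestMultitaper:
    def test_sinusoid_line(self):
        t = np.arange(1000) / FS
        ep = _epochs(np.tile(np.sin(2 * np.pi * 10 * t), (4, 1, 1)))
        ps = multitaper_psd(ep)
        np.testing.assert_allclose(ps.freqs, FREQS)
        assert ps.freqs[np.argmax(ps.power[0])] == 10.0

    def test_white_noise_is_flat(self):
        rng = np.random.default_rng(0)
        ep = _epochs(rng.standard_normal((200, 1, 1000)))
        ps = multitaper_psd(ep)
        rel = ps.power[0] / ps.power[0].mean()
        assert np.all(np.abs(rel - 1) < 0.2)

    def test_zeros(self):
        ps = multitaper_psd(_epochs(np.zeros((3, 2, 1000))))
        assert not ps.power.any()

    def test_too_little_smoothing_rejected(self):
        ep = _epochs(np.zeros((2, 1, 250)))  # 1-s epochs
        with pytest.raises(ParameterError, match="taper"):
            multitaper_psd(ep, smoothing=0.5)

    def test_incompatible_fstep_needs_zero_padding(self):
        ep = _epochs(np.zeros((2, 1, 750)))  # 3-s epochs: native 1/3 Hz
        with pytest.raises(ParameterError, match="zero_pad"):
            multitaper_psd(ep, fstep=0.5)
        ps = multitaper_psd(ep, fstep=0.5, zero_pad=True)
        np.testing.assert_allclose(ps.freqs, FREQS)


class TestNormalize:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        ps = PowerSpectrum(FREQS, rng.uniform(0.1, 2.0, (5, 87)))
        out = normalize_relative(ps)
        np.testing.assert_allclose(out.power.sum(-1), 1.0, atol=1e-9)
        assert out.normalized

    def test_idempotent_and_scale_invariant(self):
        rng = np.random.default_rng(2)
        row = rng.uniform(0.1, 2.0, 87)
        a = normalize_relative(PowerSpectrum(FREQS, row[None]))
        b = normalize_relative(PowerSpectrum(FREQS, (3.7 * row)[None]))
        again = normalize_relative(a)
        np.testing.assert_allclose(a.power, b.power)
        np.testing.assert_allclose(a.power, again.power)

    def test_zero_row_names_source(self):
        power = np.ones((3, 87))
        power[1] = 0.0
        with pytest.raises(ParameterError, match=r"\[1\]"):
            normalize_relative(PowerSpectrum(FREQS, power))


class TestDetectIaf:
    def test_single_bump(self):
        est = detect_iaf(_gaussian_spectrum(9.5))
        assert est.iaf == 9.5
        assert not est.fallback

    def test_highest_of_two_peaks(self):
        power = (np.exp(-((FREQS - 8.0) ** 2)) + 0.6 * np.exp(-((FREQS - 11.0) ** 2))
                 + 1e-6)
        ps = normalize_relative(PowerSpectrum(FREQS, power[None]))
        assert detect_iaf(ps).iaf == 8.0

    def test_monotone_spectrum_falls_back(self):
        ps = normalize_relative(PowerSpectrum(FREQS, (FREQS ** -1.0)[None]))
        est = detect_iaf(ps, search_lo=6.0, search_hi=13.0)
        assert est.fallback
        assert est.iaf == 6.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ParameterError, match="roi"):
            detect_iaf(_gaussian_spectrum(9.5), roi_sources=np.array([], dtype=int))

    def test_search_range_outside_axis_rejected(self):
        with pytest.raises(ParameterError, match="search"):
            detect_iaf(_gaussian_spectrum(9.5), search_lo=1.0)


class TestAlphaBand:
    @pytest.mark.parametrize("iaf,lo,hi", [(9.4, 6.9, 11.4), (10.0, 7.5, 12.0)])
    def test_band_rule(self, iaf, lo, hi):
        band = alpha_band_from_iaf(iaf)
        assert band.lo == pytest.approx(lo)
        assert band.hi == pytest.approx(hi)
        assert band.name == "alpha"

    def test_band_outside_analysis_range_rejected(self):
        with pytest.raises(ParameterError):
            alpha_band_from_iaf(4.4)  # lower edge would fall at 1.9 Hz


class TestBandPower:
    def test_full_axis_is_one(self):
        rng = np.random.default_rng(3)
        ps = normalize_relative(PowerSpectrum(FREQS, rng.uniform(0.1, 1, (4, 87))))
        band = BandDefinition("all", 2.0, 45.0)
        np.testing.assert_allclose(band_relative_power(ps, band), 1.0)

    def test_single_bin_mass(self):
        power = np.zeros(87)
        power[FREQS == 10.0] = 5.0
        ps = normalize_relative(PowerSpectrum(FREQS, power[None]))
        assert band_relative_power(ps, BandDefinition("alpha", 6.9, 11.4))[0] == 1.0

    def test_uniform_spectrum_counts_bins(self):
        ps = normalize_relative(PowerSpectrum(FREQS, np.ones((1, 87))))
        band = BandDefinition("b", 8.0, 12.5)  # ten bins inclusive
        assert band_relative_power(ps, band)[0] == pytest.approx(10 / 87)

    def test_partition_completeness(self):
        rng = np.random.default_rng(4)
        ps = normalize_relative(PowerSpectrum(FREQS, rng.uniform(0.1, 1, (3, 87))))
        # bands partition the bin set: edges midway between grid points
        parts = [BandDefinition("a", 2.0, 10.1), BandDefinition("b", 10.4, 30.1),
                 BandDefinition("c", 30.4, 45.0)]
        total = sum(band_relative_power(ps, b) for b in parts)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_requires_normalized(self):
        ps = PowerSpectrum(FREQS, np.ones((1, 87)))
        with pytest.raises(ParameterError, match="normalized"):
            band_relative_power(ps, BandDefinition("alpha", 6.9, 11.4))


@given(center=st.floats(7.0, 12.0))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_iaf_matches_bump_center_on_grid(center):
    grid_center = round(center * 2) / 2  # snap to the half-Hz axis
    est = detect_iaf(_gaussian_spectrum(grid_center))
    assert abs(est.iaf - grid_center) <= 0.5


def test_cohort_iaf_recovery_with_degenerate_variance():
    """iaf_sd = 0 cohorts yield detected IAFs within one bin of the mean."""
    cfg = CohortConfig(group_sizes={"noSCD": 3}, n_per_axis=2, epoch_count=12,
                       iaf_sd={"noSCD": 0.0}, seed=21)
    cohort = generate_cohort(cfg, with_signals=True)
    for s in cohort.subjects:
        ps = normalize_relative(multitaper_psd(s.epochs))
        est = detect_iaf(ps)
        assert abs(est.iaf - 9.8) <= 0.5


def test_alpha_power_monotone_in_generator_amplitude():
    """Raising the generator's alpha target raises measured alpha power."""
    means = []
    for target in (0.2, 0.45):
        cfg = CohortConfig(
            group_sizes={"noSCD": 4}, n_per_axis=2, epoch_count=10, seed=13,
            alpha_relpower_mean={"noSCD": target}, alpha_relpower_sd=0.0,
        )
        cohort = generate_cohort(cfg, with_signals=True)
        vals = []
        for s in cohort.subjects:
            ps = normalize_relative(multitaper_psd(s.epochs))
            band = alpha_band_from_iaf(9.8)
            vals.append(band_relative_power(ps, band).mean())
        means.append(np.mean(vals))
    assert means[1] > means[0]
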
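"""Spectral stage: bipolar derivation, Welch estimates, 10^A/f^B fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st_h

from lfpnet import (ElectrodeMap, EpochSpec, PowerSpectrum, Recording,
                    bipolar_pairs, compute_spectrogram, fit_aperiodic,
                    fit_powerlaw, generate_aperiodic_noise, median_spectrum,
                    separate_aperiodic)
from lfpnet.spectral import Spectrogram, mains_bands


def _emap(n, structure="PrL", region="PFC", rows=None):
    return ElectrodeMap(pd.DataFrame([{
        "channel_id": f"ch{i}", "animal_id": "a1",
        "anatomical_label": structure, "region": region,
        "row": (rows[i] if rows else i), "col": 0,
    } for i in range(n)]))


def _power_spectrum(A, B, fmax=400.0, df=0.5):
    f = np.arange(df, fmax + df / 2, df)
    return PowerSpectrum(f, 10.0 ** A / f ** B)


class TestBipolarPairs:
    def test_pair_count_all_mode(self, rng):
        rec = Recording(rng.standard_normal((4, 256)), 1000.0, 0.0,
                        [f"ch{i}" for i in range(4)])
        assert len(bipolar_pairs(rec, _emap(4))) == 6

    def test_neighbors_mode_uses_geometry(self, rng):
        rec = Recording(rng.standard_normal((4, 256)), 1000.0, 0.0,
                        [f"ch{i}" for i in range(4)])
        # chain geometry: rows 0,1,2,3 -> only consecutive pairs
        out = bipolar_pairs(rec, _emap(4, rows=[0, 1, 2, 3]), mode="neighbors")
        assert sorted(bp.pair for bp in out) == [
            ("ch0", "ch1"), ("ch1", "ch2"), ("ch2", "ch3")]

    def test_common_component_cancels_exactly(self, rng):
        common = rng.standard_normal(256)
        s = rng.standard_normal(256)
        data = np.stack([s + common, common])
        rec = Recording(data, 1000.0, 0.0, ["ch0", "ch1"])
        (bp,) = bipolar_pairs(rec, _emap(2))
        # common part cancels algebraically; recovering s costs one rounding
        assert np.allclose(bp.data, s, atol=1e-12)

    def test_identical_channels_zero_differential(self, rng):
        x = rng.standard_normal(256)
        rec = Recording(np.stack([x, x]), 1000.0, 0.0, ["ch0", "ch1"])
        (bp,) = bipolar_pairs(rec, _emap(2))
        assert np.all(bp.data == 0)

    def test_single_channel_structure_skipped(self, rng):
        rec = Recording(rng.standard_normal((1, 256)), 1000.0, 0.0, ["ch0"])
        assert bipolar_pairs(rec, _emap(1)) == []


class TestSpectrogram:
    def test_white_noise_density_level(self, rng):
        # unit variance white at 1 kHz -> one-sided density 2e-3 uV^2/Hz
        sg = compute_spectrogram(rng.standard_normal(60_000), 1000.0)
        assert sg.power.mean() == pytest.approx(2e-3, rel=0.05)

    def test_parseval_per_window(self, rng):
        x = rng.standard_normal(10_000)
        sg = compute_spectrogram(x, 1000.0, window_s=2.0)
        df = sg.frequencies[1] - sg.frequencies[0]
        for w in range(sg.power.shape[0]):
            assert sg.power[w].sum() * df == pytest.approx(1.0, rel=0.2)

    def test_sinusoid_peak_bin(self):
        t = np.arange(0, 10, 1e-3)
        sg = compute_spectrogram(np.sin(2 * np.pi * 50 * t), 1000.0)
        peak = sg.frequencies[np.argmax(sg.power.mean(axis=0))]
        assert peak == pytest.approx(50.0, abs=0.5)

    def test_constant_signal_power_at_dc(self):
        sg = compute_spectrogram(np.full(4000, 3.0), 1000.0)
        mean = sg.power.mean(axis=0)
        assert np.argmax(mean) == 0
        # Hann mainlobe leaks into the two adjacent bins; beyond that, zero
        assert mean[3:].max() < 1e-9 * mean[0]

    def test_too_short_series_raises(self, rng):
        with pytest.raises(ValueError, match="shorter"):
            compute_spectrogram(rng.standard_normal(100), 1000.0, window_s=2.0)


class TestMedianSpectrum:
    def test_single_window_identity(self, rng):
        sg = compute_spectrogram(rng.standard_normal(2000), 1000.0)
        spec = median_spectrum(sg)
        assert np.array_equal(spec.power, sg.power[0])

    def test_robust_to_transient(self):
        freqs = np.arange(1.0, 10.0)
        power = np.stack([np.ones(9), np.ones(9), 100 * np.ones(9)])
        sg = Spectrogram(times=np.array([0.0, 1.0, 2.0]), frequencies=freqs,
                         power=power)
        spec = median_spectrum(sg, EpochSpec(-0.5, 2.5))
        assert np.all(spec.power == 1.0)
        assert spec.n_windows == 3

    def test_median_mean_ratio_follows_chi_square(self, rng):
        # per-bin window PSDs are ~chi^2_2: their median is ln2 of the mean,
        # and the debiased median estimates the mean within 10%
        sg = compute_spectrogram(rng.standard_normal(120_000), 1000.0)
        mean = sg.power.mean(axis=0)
        raw = np.median(median_spectrum(sg).power / mean)
        assert raw == pytest.approx(np.log(2.0), abs=0.05)
        debiased = np.median(median_spectrum(sg, debias=True).power / mean)
        assert debiased == pytest.approx(1.0, abs=0.1)

    def test_empty_epoch_raises(self, rng):
        sg = compute_spectrogram(rng.standard_normal(2000), 1000.0)
        with pytest.raises(ValueError, match="windows"):
            median_spectrum(sg, EpochSpec(100.0, 101.0))


class TestFitPowerlaw:
    @pytest.mark.parametrize("A", [-2.0, 0.0, 1.0, 3.0])
    @pytest.mark.parametrize("B", [0.0, 0.5, 2.0, 4.0])
    def test_exact_on_noiseless_powerlaw(self, A, B):
        fit = fit_powerlaw(_power_spectrum(A, B))
        assert fit.offset == pytest.approx(A, abs=1e-10)
        assert fit.exponent == pytest.approx(B, abs=1e-10)
        assert fit.r2_loglog == pytest.approx(1.0, abs=1e-12)

    @given(st_h.floats(-3, 3), st_h.floats(0, 4))
    def test_exact_on_any_grid(self, A, B):
        f = np.geomspace(0.7, 350.0, 731)
        fit = fit_powerlaw(PowerSpectrum(f, 10.0 ** A / f ** B))
        assert fit.offset == pytest.approx(A, abs=1e-9)
        assert fit.exponent == pytest.approx(B, abs=1e-9)

    def test_flat_spectrum(self):
        fit = fit_powerlaw(_power_spectrum(0.5, 0.0))
        assert fit.offset == pytest.approx(0.5, abs=1e-12)
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_power_rejected(self):
        spec = _power_spectrum(0.0, 1.0)
        spec.power[10] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            fit_powerlaw(spec)

    def test_scale_shift_moves_offset_only(self):
        # multiplying the PSD by 10^delta shifts A by delta, leaves B alone
        base = fit_powerlaw(_power_spectrum(0.3, 1.2))
        spec = _power_spectrum(0.3, 1.2)
        spec.power *= 10.0 ** 0.7
        shifted = fit_powerlaw(spec)
        assert shifted.offset - base.offset == pytest.approx(0.7, abs=1e-10)
        assert shifted.exponent == pytest.approx(base.exponent, abs=1e-10)

    def test_steeper_f_dependence_moves_exponent_only(self):
        base = fit_powerlaw(_power_spectrum(0.3, 1.2))
        spec = _power_spectrum(0.3, 1.2)
        spec.power *= spec.frequencies ** -0.5
        steep = fit_powerlaw(spec)
        assert steep.exponent - base.exponent == pytest.approx(0.5, abs=1e-10)
        assert steep.offset == pytest.approx(base.offset, abs=1e-10)

    def test_recovery_on_shaped_noise(self):
        x = generate_aperiodic_noise(0.0, 1.5, fs=1000, duration=60, seed=21)
        sg = compute_spectrogram(x, 1000.0)
        fit = fit_powerlaw(median_spectrum(sg))
        assert fit.exponent == pytest.approx(1.5, abs=0.1)


class TestSeparateAperiodic:
    def test_pure_powerlaw_untouched(self):
        spec = _power_spectrum(1.0, 1.5)
        aperiodic, bands = separate_aperiodic(spec, mask_mains=False)
        assert bands == []
        assert np.array_equal(
            aperiodic.power,
            spec.power[(spec.frequencies >= 1) & (spec.frequencies <= 300)])

    def test_gaussian_bump_masked_and_fit_recovered(self):
        spec = _power_spectrum(1.0, 1.5)
        f = spec.frequencies
        bump = 10.0 * (10.0 ** 1.0 / 140.0 ** 1.5) * np.exp(-0.5 * ((f - 140) / 8) ** 2)
        spec.power = spec.power + bump
        aperiodic, bands = separate_aperiodic(spec, mask_mains=False)
        assert any(lo <= 140 <= hi for lo, hi in bands)
        fit = fit_powerlaw(aperiodic)
        assert fit.exponent == pytest.approx(1.5, abs=0.05)
        assert fit.offset == pytest.approx(1.0, abs=0.05)

    def test_single_spike_bin_excluded(self):
        spec = _power_spectrum(0.0, 0.0)
        spike_f = spec.frequencies[60]
        spec.power[60] *= 50
        _, bands = separate_aperiodic(spec, mask_mains=False)
        assert any(lo <= spike_f <= hi for lo, hi in bands)

    def test_mains_harmonics_always_masked(self):
        _, bands = separate_aperiodic(_power_spectrum(0.0, 1.0))
        for hz in (50, 100, 150, 200, 250, 300):
            assert any(lo <= hz <= hi for lo, hi in bands)
        assert mains_bands((1.0, 300.0))[0] == (48.0, 52.0)

    def test_never_worse_than_direct_fit_on_clean_spectra(self):
        for seed in range(5):
            x = generate_aperiodic_noise(0.5, 2.0, fs=1000, duration=30,
                                         seed=seed)
            spec = median_spectrum(compute_spectrogram(x, 1000.0))
            direct = fit_powerlaw(spec)
            sep = fit_aperiodic(spec, mask_mains=False)
            assert abs(sep.exponent - 2.0) <= abs(direct.exponent - 2.0) + 0.02
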
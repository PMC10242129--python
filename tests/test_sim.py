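"""Generator tests: spectral fidelity, mixing, determinism, drug step."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st_h
from scipy.signal import welch

from lfpnet import (DrugEffect, PowerSpectrum, SimConfig, StructureSpec,
                    expected_psd, fit_powerlaw, gaussian_mi_true,
                    gcmi_pair, generate_aperiodic_noise, mix_latent_sources,
                    simulate_experiment)
from lfpnet.sim import LatentSource, Oscillation, study_config


def _fit_noise(x, fs, fit_range=(1.0, 300.0)):
    f, p = welch(x, fs=fs, nperseg=int(2 * fs))
    return fit_powerlaw(PowerSpectrum(f, p), fit_range=fit_range)


class TestAperiodicNoise:
    def test_white_noise_has_flat_spectrum(self):
        x = generate_aperiodic_noise(0.0, 0.0, fs=1000, duration=60, seed=0)
        fit = _fit_noise(x, 1000)
        assert abs(fit.exponent) < 0.05
        assert abs(fit.offset) < 0.05

    def test_pink_exponent_recovered(self):
        x = generate_aperiodic_noise(1.0, 2.0, fs=1000, duration=60, seed=1)
        fit = _fit_noise(x, 1000)
        assert fit.exponent == pytest.approx(2.0, abs=0.1)
        assert fit.offset == pytest.approx(1.0, abs=0.2)

    def test_same_seed_bit_identical(self):
        a = generate_aperiodic_noise(0.5, 1.5, fs=500, duration=10, seed=9)
        b = generate_aperiodic_noise(0.5, 1.5, fs=500, duration=10, seed=9)
        assert np.array_equal(a, b)

    def test_error_accuracy_improves_with_duration(self):
        errs = []
        for dur in (60, 600):
            x = generate_aperiodic_noise(0.0, 1.5, fs=500, duration=dur, seed=3)
            fit = _fit_noise(x, 500, fit_range=(1.0, 200.0))
            errs.append(abs(fit.exponent - 1.5))
        assert errs[1] < errs[0]

    @pytest.mark.parametrize("bad", [
        dict(fs=0), dict(fs=-1), dict(duration=0), dict(B=-0.5),
    ])
    def test_invalid_inputs_rejected(self, bad):
        kwargs = dict(A=0.0, B=1.0, fs=100.0, duration=1.0)
        kwargs.update({k: v for k, v in bad.items() if k != "B"})
        if "B" in bad:
            kwargs["B"] = bad["B"]
        with pytest.raises(ValueError):
            generate_aperiodic_noise(**kwargs)

    def test_target_psd_is_powerlaw_on_welch_grid(self):
        freqs = np.fft.rfftfreq(2048, 1 / 1000)
        psd = expected_psd(1.0, 2.0, freqs)
        nz = freqs > 0
        assert np.allclose(psd[nz], 10.0 / freqs[nz] ** 2)
        assert psd[0] == 0.0


class TestMixing:
    def test_zero_loadings_leave_channels_independent(self, rng):
        priv = rng.standard_normal((2, 4000))
        src = rng.standard_normal((1, 4000))
        mixed = mix_latent_sources(priv, src, np.zeros((2, 1)))
        assert gcmi_pair(mixed[0], mixed[1]) < 0.01

    def test_correlation_from_loadings_matches_gaussian_mi(self, rng):
        # two unit-variance channels with rho = 0.8
        rho = 0.8
        priv = np.sqrt(1 - rho) * rng.standard_normal((2, 4000))
        src = rng.standard_normal((1, 4000))
        lam = np.full((2, 1), np.sqrt(rho))
        mixed = mix_latent_sources(priv, src, lam)
        mi = gcmi_pair(mixed[0], mixed[1])
        assert mi == pytest.approx(gaussian_mi_true(rho), abs=0.05)
        assert gaussian_mi_true(rho) == pytest.approx(0.737, abs=0.001)

    def test_dependence_monotone_in_shared_loading(self, rng):
        src = rng.standard_normal((1, 4000))
        mis = []
        for lam in (0.3, 0.6, 0.9):
            priv = np.sqrt(1 - lam ** 2) * rng.standard_normal((2, 4000))
            mixed = mix_latent_sources(priv, src, np.full((2, 1), lam))
            mis.append(gcmi_pair(mixed[0], mixed[1]))
        assert mis[0] < mis[1] < mis[2]

    def test_vanishing_private_noise_diverges(self, rng):
        src = rng.standard_normal((1, 1000))
        priv = 1e-12 * rng.standard_normal((2, 1000))
        mixed = mix_latent_sources(priv, src, np.ones((2, 1)))
        with pytest.warns(RuntimeWarning):
            assert gcmi_pair(mixed[0], mixed[1]) == np.inf

    def test_common_mode_added_identically(self, rng):
        priv = rng.standard_normal((3, 100))
        cm = rng.standard_normal(100)
        mixed = mix_latent_sources(priv, np.empty((0, 100)),
                                   np.zeros((3, 0)), common_mode=cm)
        assert np.array_equal(mixed, priv + cm[None, :])

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            mix_latent_sources(rng.standard_normal((2, 100)),
                               rng.standard_normal((1, 100)),
                               np.zeros((3, 1)))


class TestSimulateExperiment:
    def test_determinism(self):
        cfg = study_config(n_structures=2, channels_per_structure=4,
                           duration_pre=5, duration_post=5, rng_seed=11)
        rec1, _, _ = simulate_experiment(cfg)
        rec2, _, _ = simulate_experiment(cfg)
        assert np.array_equal(rec1.data, rec2.data)

    def test_span_and_metadata(self):
        cfg = study_config(n_structures=2, channels_per_structure=4,
                           duration_pre=10, duration_post=20, rng_seed=0)
        rec, emap, truth = simulate_experiment(cfg)
        assert rec.t0 == -10
        assert rec.t_end == pytest.approx(20)
        assert rec.n_channels == 8 == len(emap)
        assert set(truth.true_offset) == {"baseline", "post"}

    def test_common_mode_identical_across_channels(self):
        # with no private/source power the signal is the common mode alone
        cfg = SimConfig(
            n_channels=3,
            structures=[StructureSpec("PrL", "PFC", (0, 1, 2))],
            fs=500.0, duration_pre=2.0, duration_post=2.0,
            offsets=np.full(3, -20.0), exponents=np.full(3, 1.0),
            common_mode_amplitude=4.0, rng_seed=5,
        )
        rec, _, _ = simulate_experiment(cfg)
        spread = np.abs(rec.data - rec.data[0]).max()
        assert spread < 1e-6 * np.abs(rec.data).max()

    def test_offset_step_recovered(self):
        cfg = study_config(drug_effect=DrugEffect(delta_offset=0.3),
                           n_structures=1, channels_per_structure=2,
                           duration_pre=60, duration_post=60,
                           common_mode_amplitude=0.0, rng_seed=2)
        rec, _, truth = simulate_experiment(cfg)
        pre = rec.data[0, :60_000]
        post = rec.data[0, 60_000:]
        d = (_fit_noise(post, 1000).offset - _fit_noise(pre, 1000).offset)
        expected = truth.true_offset["post"][0] - truth.true_offset["baseline"][0]
        assert d == pytest.approx(expected, abs=0.1)
        assert expected == pytest.approx(0.3, abs=1e-12)  # g = 1: no mixture term

    def test_coupling_scale_reduces_mi_ratio(self, rng):
        cfg = study_config(drug_effect=DrugEffect(coupling_scale=0.5),
                           n_structures=1, channels_per_structure=2,
                           duration_pre=30, duration_post=30,
                           common_mode_amplitude=0.0, rng_seed=4)
        rec, _, truth = simulate_experiment(cfg)
        pre = rec.data[:, :30_000]
        post = rec.data[:, 30_000:]
        mi_pre = gcmi_pair(pre[0], pre[1])
        mi_post = gcmi_pair(post[0], post[1])
        assert truth.coupling["post"][0, 1] == pytest.approx(
            0.5 * truth.coupling["baseline"][0, 1])
        assert mi_post / mi_pre < 1.0

    def test_null_effect_epochs_exchangeable(self, small_study):
        _, rec, _, truth = small_study
        assert np.array_equal(truth.true_offset["baseline"],
                              truth.true_offset["post"])
        pre = rec.data[0, :60_000]
        post = rec.data[0, 60_000:]
        f_pre = _fit_noise(pre, 1000)
        f_post = _fit_noise(post, 1000)
        assert f_post.offset - f_pre.offset == pytest.approx(0.0, abs=0.1)
        assert f_post.exponent - f_pre.exponent == pytest.approx(0.0, abs=0.1)


class TestConfigValidation:
    def _base(self, **over):
        kw = dict(
            n_channels=2,
            structures=[StructureSpec("PrL", "PFC", (0, 1))],
            fs=500.0, duration_pre=1.0, duration_post=1.0,
            offsets=np.zeros(2), exponents=np.ones(2),
        )
        kw.update(over)
        return kw

    def test_channel_not_in_any_structure(self):
        with pytest.raises(ValueError, match="exactly one structure"):
            SimConfig(**self._base(structures=[StructureSpec("PrL", "PFC", (0,))]))

    def test_oscillation_beyond_nyquist(self):
        osc = Oscillation(240.0, 40.0, 1.0, (0,))
        with pytest.raises(ValueError, match="Nyquist"):
            SimConfig(**self._base(oscillations=[osc]))

    def test_negative_coupling_scale(self):
        with pytest.raises(ValueError, match="coupling_scale"):
            SimConfig(**self._base(drug_effect=DrugEffect(coupling_scale=-1)))

    def test_overloaded_channel(self):
        src = LatentSource(loadings=(0.9, 0.9), exponent=1.0)
        with pytest.raises(ValueError, match="loadings"):
            SimConfig(**self._base(latent_sources=[src, src]))

    @given(st_h.floats(min_value=-3, max_value=3),
           st_h.floats(min_value=0, max_value=4))
    def test_ground_truth_coupling_symmetric(self, da, db):
        cfg = study_config(drug_effect=DrugEffect(da, db, 0.5),
                           n_structures=2, channels_per_structure=2,
                           duration_pre=1, duration_post=1)
        _, _, truth = simulate_experiment(cfg)
        for ep in ("baseline", "post"):
            c = truth.coupling[ep]
            assert np.allclose(c, c.T)
            assert np.all(np.diag(c) >= 0)
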
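"""Amplitude-gradient saliency: chain rule, band aggregation, grouping."""

import numpy as np
import pytest

from eegage import (DEFAULT_BANDS, ModelConfig, TCNRegressor,
                    amplitude_gradients, band_aggregate, group_saliency,
                    recording_saliency)
from eegage.saliency import BandDefinition, amplitude_gradients_from_time


def _small_model(n_ch=3, seed=1):
    mc = ModelConfig(n_channels=n_ch, n_blocks=2, kernel_size=3, n_filters=8,
                     dropout=0.0)
    return TCNRegressor(mc, seed=seed), mc


class TestAmplitudeGradients:
    def test_constant_model_zero_gradients(self):
        model, mc = _small_model()
        model.head.W[...] = 0.0
        crop = np.random.default_rng(0).normal(size=(3, mc.receptive_field))
        g = amplitude_gradients(model, crop)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_channel_mean_model_dc_only(self):
        """Output = mean of channel 0: only the DC bin of channel 0 has a
        nonzero amplitude gradient."""
        n = 64
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, n))
        g_time = np.zeros((2, n))
        g_time[0] = 1.0 / n
        g = amplitude_gradients_from_time(g_time, x)
        # DC of a real signal has phase 0 or pi; |grad| = 1/n * sign factor
        assert abs(g[0, 0]) == pytest.approx(1.0 / n)
        np.testing.assert_allclose(g[0, 1:], 0.0, atol=1e-12)
        np.testing.assert_allclose(g[1], 0.0, atol=1e-12)

    def test_matches_finite_differences(self):
        model, mc = _small_model()
        rf = mc.receptive_field
        rng = np.random.default_rng(2)
        crop = rng.standard_normal((3, rf))
        grad = amplitude_gradients(model, crop)
        X = np.fft.rfft(crop, axis=1)
        amps, phases = np.abs(X), np.angle(X)
        eps = 1e-4
        coords = [(0, 1), (1, 3), (2, 5), (0, 4), (1, 2)]
        for c, f in coords:
            outs = []
            for s in (eps, -eps):
                a2 = amps.copy()
                a2[c, f] += s
                x2 = np.fft.irfft(a2 * np.exp(1j * phases), n=rf, axis=1)
                outs.append(model.forward(x2[None], cache=False)[0, 0])
            fd = (outs[0] - outs[1]) / (2 * eps)
            assert abs(grad[c, f] - fd) / max(abs(fd), 1e-12) < 1e-3

    def test_linearity_in_time_gradient(self):
        """Gradient map of a sum of models = sum of the gradient maps."""
        n = 32
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, n))
        g1 = rng.normal(size=(2, n))
        g2 = rng.normal(size=(2, n))
        lhs = amplitude_gradients_from_time(g1 + g2, x)
        rhs = (amplitude_gradients_from_time(g1, x)
               + amplitude_gradients_from_time(g2, x))
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_sign_convention_by_perturbation(self):
        """Increasing amplitude at a negative-gradient coordinate lowers the
        output; at a positive-gradient coordinate it raises it."""
        model, mc = _small_model(seed=7)
        rf = mc.receptive_field
        crop = np.random.default_rng(4).standard_normal((3, rf))
        grad = amplitude_gradients(model, crop)
        X = np.fft.rfft(crop, axis=1)
        amps, phases = np.abs(X), np.angle(X)
        flat = np.argsort(np.abs(grad[:, 1:-1]).ravel())[-3:]
        base = model.forward(crop[None], cache=False)[0, 0]
        for k in flat:
            c, f = np.unravel_index(k, grad[:, 1:-1].shape)
            f = f + 1
            a2 = amps.copy()
            a2[c, f] += 1e-3
            x2 = np.fft.irfft(a2 * np.exp(1j * phases), n=rf, axis=1)
            delta = model.forward(x2[None], cache=False)[0, 0] - base
            assert np.sign(delta) == np.sign(grad[c, f])


class TestBandAggregate:
    def test_uniform_bins(self):
        n, sfreq = 200, 100.0
        n_bins = n // 2 + 1
        grads = np.full((4, n_bins), 3.14)
        out = band_aggregate(grads, n, sfreq)
        np.testing.assert_allclose(out, 3.14)

    def test_single_bin_lands_in_alpha(self):
        n, sfreq = 200, 100.0
        grads = np.zeros((2, n // 2 + 1))
        f_idx = int(10.0 * n / sfreq)   # 10 Hz bin
        grads[0, f_idx] = 5.0
        out = band_aggregate(grads, n, sfreq)
        names = [b.name for b in DEFAULT_BANDS]
        alpha = names.index("alpha")
        assert out[0, alpha] != 0.0
        mask = np.ones(len(names), bool)
        mask[alpha] = False
        np.testing.assert_allclose(out[0, mask], 0.0, atol=1e-12)
        np.testing.assert_allclose(out[1], 0.0, atol=1e-12)

    def test_matches_masked_mean_oracle(self):
        n, sfreq = 128, 100.0
        rng = np.random.default_rng(5)
        grads = rng.normal(size=(3, n // 2 + 1))
        freqs = np.fft.rfftfreq(n, 1 / sfreq)
        out = band_aggregate(grads, n, sfreq)
        for bi, band in enumerate(DEFAULT_BANDS):
            mask = (freqs >= band.lo) & (freqs < band.hi)
            np.testing.assert_allclose(out[:, bi], grads[:, mask].mean(axis=1))

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_aggregate(np.zeros((1, 65)), 128, 100.0,
                           bands=(BandDefinition("hf", 40.0, 80.0),))


class TestGroupSaliency:
    def test_single_subject_reduces_to_recording_map(self):
        model, mc = _small_model()
        sig = np.random.default_rng(6).normal(
            size=(3, mc.receptive_field + 40)).astype(np.float32)
        rec = {"signal": sig, "subject_id": "s1", "pathology": False}
        maps = group_saliency([model], [rec], sfreq=100.0)
        expected = recording_saliency(model, sig, 100.0)
        np.testing.assert_allclose(maps["non_pathological"], expected)
        assert maps["pathological"] is None

    def test_identical_recordings_zero_difference(self):
        # receptive field of 57 samples so every band contains DFT bins
        mc = ModelConfig(n_channels=3, n_blocks=3, kernel_size=5,
                         n_filters=8, dropout=0.0)
        model = TCNRegressor(mc, seed=1)
        sig = np.random.default_rng(7).normal(
            size=(3, mc.receptive_field + 40)).astype(np.float32)
        recs = [
            {"signal": sig, "subject_id": "a", "pathology": False},
            {"signal": sig.copy(), "subject_id": "b", "pathology": True},
        ]
        maps = group_saliency([model], recs, sfreq=100.0)
        np.testing.assert_allclose(maps["difference"], 0.0, atol=1e-10)


def test_trained_model_attends_to_alpha(study_trait):
    """The synthetic age signal lives in the alpha rhythm; the trained
    decoder's saliency should weight the alpha band strongly at occipital
    channels, where the planted oscillation is largest."""
    art = study_trait.fe_artifacts[0]
    model, stats = art["model"], art["stats"]
    gaps = study_trait.gaps
    from eegage.preproc import apply_normalization
    # rebuild two held-out standardized recordings from the study manifest
    from eegage import CohortConfig, generate_cohort
    cfg = CohortConfig(n_subjects=3, duration_s=30.0, trait_sd=0.0,
                       pathology_fraction=0.0, seed=900)
    recs, _ = generate_cohort(cfg)
    records = [{"signal": apply_normalization(stats, r.signal),
                "subject_id": r.subject_id, "pathology": False}
               for r in recs]
    maps = group_saliency([model], records, sfreq=100.0, max_crops=8)
    m = np.abs(maps["non_pathological"])
    names = [b.name for b in DEFAULT_BANDS]
    channels = cfg.channels
    # strongest alpha-band response should sit on an occipital channel
    alpha = m[:, names.index("alpha")]
    assert channels[int(np.argmax(alpha))] in ("O1", "O2")
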
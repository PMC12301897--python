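"""Convolutional age regressor: crops, augmentation, gradients, CV protocol."""

import numpy as np
import pytest

from eegage import (ClassError, LeakageError, ModelConfig, TCNRegressor,
                    TooShortError, TrainConfig, channel_dropout, make_crops,
                    predict_recording, run_final_evaluation, subject_folds,
                    train)
from eegage.model import predict_crop_outputs
from eegage.nn import sigmoid
from eegage.preproc import NormalizationStats


def _stats(n_ch=2, age_min=0.0, age_max=100.0):
    return NormalizationStats(np.zeros(n_ch), np.ones(n_ch), age_min, age_max)


class TestMakeCrops:
    def test_counts(self):
        sig = np.random.default_rng(0).normal(size=(2, 1000))
        assert make_crops(sig, 1000).shape[0] == 1
        assert make_crops(sig, 600).shape == (401, 2, 600)

    def test_one_sample_stride(self):
        sig = np.arange(10, dtype=float)[None, :]
        crops = make_crops(sig, 4)
        for i in range(crops.shape[0]):
            np.testing.assert_array_equal(crops[i, 0], sig[0, i:i + 4])

    def test_too_short(self):
        with pytest.raises(TooShortError):
            make_crops(np.zeros((2, 5)), 6)


class TestChannelDropout:
    def test_p_zero_identity(self):
        crops = np.random.default_rng(1).normal(size=(4, 3, 10))
        out = channel_dropout(crops, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out, crops)

    def test_zeroed_fraction(self):
        crops = np.ones((2000, 5, 4))
        out = channel_dropout(crops, 0.3, np.random.default_rng(2))
        frac = np.mean(out[:, :, 0] == 0.0)
        assert abs(frac - 0.3) < 0.02

    def test_reproducible_mask(self):
        crops = np.ones((10, 3, 4))
        a = channel_dropout(crops, 0.5, np.random.default_rng(7))
        b = channel_dropout(crops, 0.5, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Input gradient of the full network against central differences."""
        mc = ModelConfig(n_channels=2, n_blocks=2, kernel_size=3,
                         n_filters=6, dropout=0.0)
        model = TCNRegressor(mc, seed=3)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, mc.receptive_field))
        g = model.input_gradient(x[None])[0]
        eps = 1e-5
        for c, t in [(0, 0), (1, 3), (0, 7), (1, mc.receptive_field - 1)]:
            xp, xm = x.copy(), x.copy()
            xp[c, t] += eps
            xm[c, t] -= eps
            fd = (model.forward(xp[None], cache=False)[0, 0]
                  - model.forward(xm[None], cache=False)[0, 0]) / (2 * eps)
            assert g[c, t] == pytest.approx(fd, rel=1e-5, abs=1e-10)

    def test_weight_gradients_match_finite_differences(self):
        mc = ModelConfig(n_channels=2, n_blocks=1, kernel_size=3,
                         n_filters=4, dropout=0.0)
        model = TCNRegressor(mc, seed=5)
        x = np.random.default_rng(1).standard_normal((1, 2, mc.receptive_field))
        y = model.forward(x)
        model.backward(np.ones_like(y))
        conv = model.blocks[0].conv1
        eps = 1e-4
        for idx in [(0, 0, 0), (1, 1, 2), (3, 0, 1)]:
            orig = conv.W[idx]
            conv.W[idx] = orig + eps
            fp = model.forward(x, cache=False)[0, 0]
            conv.W[idx] = orig - eps
            fm = model.forward(x, cache=False)[0, 0]
            conv.W[idx] = orig
            assert conv.gW[idx] == pytest.approx((fp - fm) / (2 * eps), rel=1e-2)


class TestPrediction:
    def test_constant_model_predicts_midrange(self):
        mc = ModelConfig(n_channels=2, n_blocks=1, kernel_size=3, n_filters=4,
                         dropout=0.0)
        model = TCNRegressor(mc, seed=0)
        model.head.W[...] = 0.0
        model.head.b[...] = 0.0          # sigmoid(0) = 0.5
        sig = np.random.default_rng(2).normal(size=(2, 200)).astype(np.float32)
        assert predict_recording(model, sig, _stats()) == pytest.approx(50.0)

    def test_full_pass_equals_materialized_crops(self):
        """Dense (cropped-decoding) outputs equal brute-force per-crop calls."""
        mc = ModelConfig(n_channels=3, n_blocks=2, kernel_size=3, n_filters=8,
                         dropout=0.0)
        model = TCNRegressor(mc, seed=4)
        rf = mc.receptive_field
        sig = np.random.default_rng(3).normal(size=(3, rf + 50)).astype(np.float32)
        dense = predict_crop_outputs(model, sig)
        crops = make_crops(sig, rf)
        brute = model.forward(crops, cache=False)[:, 0]
        assert dense.shape == (51,)
        np.testing.assert_allclose(dense, brute, rtol=1e-5, atol=1e-6)

    def test_too_short_recording(self):
        mc = ModelConfig(n_channels=2, n_blocks=2, kernel_size=5, n_filters=4)
        model = TCNRegressor(mc, seed=0)
        with pytest.raises(TooShortError):
            predict_recording(model, np.zeros((2, 10), dtype=np.float32),
                              _stats())


class TestTraining:
    def test_single_subject_overfit(self):
        """Capacity sanity check: the loss on one recording goes below 0.05."""
        mc = ModelConfig(n_channels=2, n_blocks=2, kernel_size=3, n_filters=8,
                         dropout=0.0)
        sig = np.random.default_rng(5).normal(size=(2, 400)).astype(np.float32)
        tc = TrainConfig(epochs=40, batch_size=16, crops_per_recording=64,
                         channel_dropout_p=0.0, lr=3e-3, seed=1)
        _, history = train([sig], np.array([0.3]), mc, tc)
        assert history[-1] < 0.05

    def test_seeded_determinism(self):
        mc = ModelConfig(n_channels=2, n_blocks=1, kernel_size=3, n_filters=4)
        sigs = [np.random.default_rng(6).normal(size=(2, 200)).astype(np.float32)]
        tc = TrainConfig(epochs=3, batch_size=16, crops_per_recording=8, seed=9)
        _, h1 = train(sigs, np.array([0.5]), mc, tc)
        _, h2 = train(sigs, np.array([0.5]), mc, tc)
        assert h1 == h2

    def test_too_short_training_recording(self):
        mc = ModelConfig(n_channels=2, n_blocks=2, kernel_size=5, n_filters=4)
        tc = TrainConfig(epochs=1)
        with pytest.raises(TooShortError):
            train([np.zeros((2, 10), dtype=np.float32)], np.array([0.5]), mc, tc)


class TestSplitting:
    @pytest.mark.parametrize("seed", range(50))
    def test_subject_folds_partition_fuzz(self, seed):
        subjects = [f"s{i}" for i in range(23)]
        folds = subject_folds(subjects, 5, seed)
        flat = [s for fold in folds for s in fold]
        assert sorted(flat) == sorted(subjects)
        assert len(set(flat)) == len(flat)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_even_split(self):
        folds = subject_folds([f"s{i}" for i in range(10)], 5, 0)
        assert all(len(f) == 2 for f in folds)

    def test_too_few_subjects(self):
        with pytest.raises(ClassError):
            subject_folds(["a", "b"], 5, 0)

    def test_final_evaluation_leakage_guard(self, tiny_cohort):
        _, recordings, _ = tiny_cohort
        mc = ModelConfig(n_channels=8, n_blocks=1, kernel_size=3, n_filters=4)
        tc = TrainConfig(epochs=1, crops_per_recording=2)
        sigs = [r.signal.astype(np.float32) for r in recordings]
        with pytest.raises(LeakageError):
            run_final_evaluation(recordings, sigs, recordings[:2], sigs[:2],
                                 mc, tc, n_runs=1)


def test_cv_prediction_protocol(study_trait):
    """Each training-split recording is predicted exactly once, out of fold,
    and all recordings of one subject share a fold."""
    gaps = study_trait.gaps
    cv = gaps[gaps["split"].str.startswith("cv_fold")]
    assert cv["recording_id"].is_unique
    fold_of = cv.groupby("subject_id")["split"].nunique()
    assert (fold_of == 1).all()
    fe = gaps[gaps["split"] == "final_eval"]
    assert set(cv["subject_id"]).isdisjoint(set(fe["subject_id"]))
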
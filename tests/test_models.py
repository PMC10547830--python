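"""Classifier families: fitting power, contracts, determinism, features."""

import time

import numpy as np
import pytest

import eegleak as el
from eegleak import _nn
from eegleak.models import ModelConfig, baseline_features, train


class TestConfig:
    def test_family_defaults(self):
        compact = ModelConfig(family="compact_cnn")
        deep = ModelConfig(family="deep_cnn")
        assert compact.learning_rate == 1e-3 and compact.dropout == 0.5
        assert deep.learning_rate == 1e-4 and deep.dropout == 0.1
        assert compact.batch_size == 5
        assert ModelConfig(family="compact_cnn", scale="paper").epochs == 300

    @pytest.mark.parametrize("kw", [
        dict(family="resnet"), dict(learning_rate=-1.0), dict(dropout=1.5),
        dict(batch_size=0), dict(scale="huge"),
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(el.ConfigurationError):
            ModelConfig(**kw)


class TestTrainingContracts:
    def test_single_class_rejected(self, separable_trialset):
        ts = separable_trialset
        m = ts.labels == el.PATIENT
        with pytest.raises(el.ConfigurationError):
            train(ts.trials[m], ts.labels[m], ModelConfig(family="spectral_baseline"),
                  ts.fs_hz)

    def test_non_finite_input_rejected(self, separable_trialset):
        ts = separable_trialset
        bad = ts.trials[:10].copy()
        bad[0, 0, 0] = np.nan
        with pytest.raises(el.ConfigurationError):
            train(bad, ts.labels[:10], ModelConfig(family="spectral_baseline"), ts.fs_hz)

    def test_probabilities_normalized_and_shapes_enforced(self, separable_trialset):
        ts = separable_trialset
        model = train(ts.trials, ts.labels,
                      ModelConfig(family="deep_cnn", epochs=2, seed=0), ts.fs_hz)
        proba, labels = model.predict(ts.trials[:16])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert set(labels) <= {el.PATIENT, el.CONTROL}
        with pytest.raises(el.ConfigurationError):
            model.predict(ts.trials[:4, :, :-1])

    def test_training_is_deterministic_given_seed(self, separable_trialset):
        ts = separable_trialset
        cfg = ModelConfig(family="compact_cnn", epochs=3, seed=42)
        _, la = train(ts.trials, ts.labels, cfg, ts.fs_hz).predict(ts.trials)
        _, lb = train(ts.trials, ts.labels, cfg, ts.fs_hz).predict(ts.trials)
        np.testing.assert_array_equal(la, lb)


class TestFittingPower:
    def test_spectral_baseline_fits_separable_data_fast(self, separable_trialset):
        ts = separable_trialset
        t0 = time.time()
        model = train(ts.trials, ts.labels, ModelConfig(family="spectral_baseline"),
                      ts.fs_hz)
        _, labels = model.predict(ts.trials)
        assert time.time() - t0 < 5.0
        assert el.balanced_accuracy(ts.labels, labels) > 90.0

    def test_compact_cnn_fits_separable_data(self, separable_trialset):
        ts = separable_trialset
        model = train(ts.trials, ts.labels,
                      ModelConfig(family="compact_cnn", epochs=100, seed=0), ts.fs_hz)
        _, labels = model.predict(ts.trials)
        assert el.balanced_accuracy(ts.labels, labels) > 90.0

    def test_deep_cnn_fits_separable_data(self, separable_trialset):
        ts = separable_trialset
        model = train(ts.trials, ts.labels,
                      ModelConfig(family="deep_cnn", epochs=40, seed=0), ts.fs_hz)
        _, labels = model.predict(ts.trials)
        assert el.balanced_accuracy(ts.labels, labels) > 90.0


class TestPenultimateFeatures:
    def test_compact_feature_dim_at_reference_scale(self, rng):
        """Published filter counts on a 10-s, 200 Hz, 64-channel input give
        a 992-dimensional flattened convolutional representation."""
        x = rng.standard_normal((4, 64, 2000))
        y = np.array([el.PATIENT, el.PATIENT, el.CONTROL, el.CONTROL])
        model = train(x, y, ModelConfig(family="compact_cnn", scale="paper",
                                        epochs=1, seed=0), fs_hz=200.0)
        assert model.feature_dim == 992
        feats = model.penultimate_features(x)
        assert feats.shape == (4, 992)
        assert np.all(np.isfinite(feats))

    def test_duplicate_trials_have_identical_features(self, separable_trialset):
        ts = separable_trialset
        model = train(ts.trials, ts.labels,
                      ModelConfig(family="compact_cnn", epochs=2, seed=1), ts.fs_hz)
        dup = np.concatenate([ts.trials[:3], ts.trials[:3]])
        feats = model.penultimate_features(dup)
        np.testing.assert_array_equal(feats[:3], feats[3:])

    def test_within_subject_features_are_closer(self, fingerprint_cohort):
        """Crops of one subject cluster in feature space when subjects
        carry spectral fingerprints."""
        _, recs = fingerprint_cohort
        ts = el.build_trialset(recs, el.AugmentationParams(10.0, 0.0))
        model = train(ts.trials, ts.labels, ModelConfig(family="spectral_baseline"),
                      ts.fs_hz)
        feats = model.penultimate_features(ts.trials)
        from eegleak.features import within_between_dispersion
        within, between = within_between_dispersion(feats, ts.subject_ids)
        assert within < between

    def test_baseline_features_are_band_powers(self, separable_trialset):
        ts = separable_trialset
        feats = baseline_features(ts.trials, ts.fs_hz)
        assert feats.shape[0] == ts.n_trials
        assert np.all(np.isfinite(feats))


class TestLayerGradients:
    def test_conv_time_backward_matches_brute_force(self, rng):
        """Analytic gradients of the temporal convolution against a direct
        nested-loop reference on a tiny tensor."""
        N, Fin, H, T, Fout, K = 2, 3, 2, 9, 4, 5
        layer = _nn.ConvTime(Fin, Fout, K, np.random.default_rng(0))
        x = rng.standard_normal((N, Fin, H, T)).astype(np.float32)
        out = layer.forward(x, train=True)
        pl = (K - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (pl, K - 1 - pl)))
        ref = np.zeros_like(out)
        for n in range(N):
            for o in range(Fout):
                for h in range(H):
                    for t in range(T):
                        ref[n, o, h, t] = sum(
                            layer.w[o, f, k] * xp[n, f, h, t + k]
                            for f in range(Fin) for k in range(K)) + layer.b[o]
        np.testing.assert_allclose(out, ref, atol=1e-5)

        d_out = rng.standard_normal(out.shape).astype(np.float32)
        dx = layer.backward(d_out)
        dW = np.zeros_like(layer.w)
        for o in range(Fout):
            for f in range(Fin):
                for k in range(K):
                    dW[o, f, k] = sum(d_out[n, o, h, t] * xp[n, f, h, t + k]
                                      for n in range(N) for h in range(H)
                                      for t in range(T))
        np.testing.assert_allclose(layer.grads[0], dW, atol=1e-4)
        dx_ref = np.zeros_like(x)
        for n in range(N):
            for f in range(Fin):
                for h in range(H):
                    for tt in range(T):
                        s = 0.0
                        for o in range(Fout):
                            for k in range(K):
                                t_out = tt - k + pl
                                if 0 <= t_out < T:
                                    s += layer.w[o, f, k] * d_out[n, o, h, t_out]
                        dx_ref[n, f, h, tt] = s
        np.testing.assert_allclose(dx, dx_ref, atol=1e-4)
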
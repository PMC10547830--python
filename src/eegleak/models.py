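"""The two CNN classifiers and a fast spectral baseline.

Three model families, trained per CV fold:

``compact_cnn``
    An EEGNet-style compact network: temporal convolution, depthwise
    spatial convolution across electrodes, a separable (depthwise temporal
    + pointwise) convolution, ELU activations, average pooling by 4 then 8,
    dropout 0.5, Adam at 1e-3.  With the published filter counts (F1=8,
    D=2, F2=16, temporal kernel = fs/2) the flattened output of the last
    convolutional block on a 10-s, 200 Hz input is 992-dimensional.

``deep_cnn``
    A CNN-13-style deeper network: 5 convolutional layers + 5 max-pooling
    layers + 3 fully-connected layers, leaky-ReLU activations, dropout 0.1,
    Adam at 1e-4.  EEG channels enter as input feature maps of a 1-D
    temporal convolution stack.

``spectral_baseline``
    A deterministic filter-bank model: per-channel log band power in 2-Hz
    sub-bands (Welch), standardized, classified by logistic regression.
    Orders of magnitude faster than the CNNs and subject to the same
    leakage mechanisms, so the evaluation grid can be exercised cheaply.

All families share batch size 5, cross-entropy loss and the Adam
optimizer (the baseline's logistic head is fitted by lbfgs instead).
Inputs are z-scored per trial and channel inside ``train``/``predict``
for the CNN families; the baseline consumes raw crops, since band power
is its feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import welch
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from . import _nn
from .augment import TrialSet
from .cohort import CONTROL, PATIENT
from .errors import ConfigurationError

FAMILIES = ("compact_cnn", "deep_cnn", "spectral_baseline")

_FAMILY_DEFAULTS = {
    "compact_cnn": dict(learning_rate=1e-3, dropout=0.5),
    "deep_cnn": dict(learning_rate=1e-4, dropout=0.1),
    "spectral_baseline": dict(learning_rate=1.0, dropout=0.0),
}


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one model family.

    ``scale='paper'`` uses the published filter counts and 300 training
    epochs; ``scale='desk'`` shrinks filters and epochs so a fold trains
    in seconds on one CPU (intended for tests and pilot runs).
    """

    family: str = "compact_cnn"
    scale: str = "desk"
    learning_rate: Optional[float] = None
    dropout: Optional[float] = None
    batch_size: int = 5
    epochs: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.scale not in ("paper", "desk"):
            raise ConfigurationError(f"scale must be 'paper' or 'desk', got {self.scale!r}")
        defaults = _FAMILY_DEFAULTS[self.family]
        if self.learning_rate is None:
            object.__setattr__(self, "learning_rate", defaults["learning_rate"])
        if self.dropout is None:
            object.__setattr__(self, "dropout", defaults["dropout"])
        if self.epochs is None:
            object.__setattr__(self, "epochs", 300 if self.scale == "paper" else 30)
        if self.learning_rate <= 0:
            raise ConfigurationError(f"learning_rate must be > 0, got {self.learning_rate}")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigurationError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")

    def with_seed(self, seed: int) -> "ModelConfig":
        return replace(self, seed=seed)


def _zscore(x: np.ndarray) -> np.ndarray:
    """Per-trial, per-channel standardisation."""
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    return ((x - mu) / np.maximum(sd, 1e-8)).astype(np.float32)


def _compact_net(n_channels: int, n_samples: int, fs_hz: float, cfg: ModelConfig,
                 rng: np.random.Generator) -> tuple[_nn.Sequential, int, int]:
    """EEGNet-style stack; returns (net, feature_dim, penultimate_index)."""
    if cfg.scale == "paper":
        f1, depth, f2 = 8, 2, 16
        sep_k = 16
    else:
        f1, depth, f2 = 4, 2, 8
        sep_k = 8
    kern = max(2, int(fs_hz) // 2)
    layers: list[_nn.Layer] = [
        _nn.ConvTime(1, f1, kern, rng, bias=False),
        _nn.BatchNorm(f1),
        _nn.DepthwiseSpatial(f1, depth, n_channels, rng),
        _nn.BatchNorm(f1 * depth),
        _nn.ELU(),
        _nn.AvgPoolTime(4),
        _nn.Dropout(cfg.dropout, rng),
        _nn.DepthwiseTime(f1 * depth, sep_k, rng),
        _nn.ConvTime(f1 * depth, f2, 1, rng, bias=False),
        _nn.BatchNorm(f2),
        _nn.ELU(),
        _nn.AvgPoolTime(8),
        _nn.Dropout(cfg.dropout, rng),
        _nn.Flatten(),
    ]
    feature_dim = f2 * ((n_samples // 4) // 8)
    layers.append(_nn.Dense(feature_dim, 2, rng))
    return _nn.Sequential(layers), feature_dim, len(layers) - 1


def _deep_net(n_channels: int, n_samples: int, cfg: ModelConfig,
              rng: np.random.Generator) -> tuple[_nn.Sequential, int, int]:
    """CNN-13-style stack: 5 conv + 5 pool + 3 dense layers."""
    if cfg.scale == "paper":
        filters = (16, 32, 64, 128, 256)
        hidden = (128, 64)
    else:
        filters = (4, 8, 8, 16, 16)
        hidden = (32, 16)
    layers: list[_nn.Layer] = []
    f_in = n_channels
    t = n_samples
    for f_out in filters:
        layers += [_nn.ConvTime(f_in, f_out, 5, rng), _nn.LeakyReLU(), _nn.MaxPoolTime(2)]
        f_in = f_out
        t //= 2
    flat = f_in * t
    layers += [
        _nn.Flatten(),
        _nn.Dense(flat, hidden[0], rng),
        _nn.LeakyReLU(),
        _nn.Dropout(cfg.dropout, rng),
        _nn.Dense(hidden[0], hidden[1], rng),
        _nn.LeakyReLU(),
        _nn.Dense(hidden[1], 2, rng),
    ]
    return _nn.Sequential(layers), hidden[1], len(layers) - 1


class _BandPowerExtractor:
    """Per-channel log power in 2-Hz sub-bands between 1 Hz and Nyquist."""

    def __init__(self, fs_hz: float, band_width_hz: float = 2.0,
                 f_max_hz: float = 40.0) -> None:
        self.fs = fs_hz
        top = min(f_max_hz, fs_hz / 2.0)
        edges = np.arange(1.0, top + 1e-9, band_width_hz)
        if edges.size < 2:
            edges = np.array([0.0, fs_hz / 2.0])
        self.edges = edges

    def __call__(self, x: np.ndarray) -> np.ndarray:
        n, c, t = x.shape
        nperseg = min(t, int(2 * self.fs))
        freqs, psd = welch(x, fs=self.fs, nperseg=nperseg, axis=-1)
        feats = []
        for lo, hi in zip(self.edges[:-1], self.edges[1:]):
            m = (freqs >= lo) & (freqs < hi)
            feats.append(np.log10(psd[..., m].sum(axis=-1) + 1e-12))
        return np.stack(feats, axis=-1).reshape(n, -1)


@dataclass
class TrainedModel:
    """A fitted classifier with its config and feature extractor."""

    config: ModelConfig
    input_shape: tuple[int, int]  # (n_channels, window_samples)
    feature_dim: int
    classes: tuple[str, str] = (CONTROL, PATIENT)
    _net: Optional[_nn.Sequential] = field(default=None, repr=False)
    _penultimate_idx: int = 0
    _extractor: Optional[_BandPowerExtractor] = field(default=None, repr=False)
    _scaler: Optional[StandardScaler] = field(default=None, repr=False)
    _logreg: Optional[LogisticRegression] = field(default=None, repr=False)
    fs_hz: float = 0.0

    def _check_shape(self, trials: np.ndarray) -> np.ndarray:
        trials = np.asarray(trials)
        if trials.ndim != 3 or trials.shape[1:] != self.input_shape:
            raise ConfigurationError(
                f"input shape {trials.shape[1:]} does not match the model's "
                f"training shape {self.input_shape}"
            )
        return trials

    def _net_input(self, trials: np.ndarray) -> np.ndarray:
        z = _zscore(trials)
        if self.config.family == "compact_cnn":
            return z[:, None, :, :]  # (N, 1, C, T)
        return z[:, :, None, :]  # deep net: channels as feature maps (N, C, 1, T)

    def predict_proba_from_features(self, features: np.ndarray) -> np.ndarray:
        """Baseline-only fast path: probabilities from precomputed band
        powers (as returned by :func:`baseline_features`)."""
        if self.config.family != "spectral_baseline":
            raise ConfigurationError(
                "predict_proba_from_features is only available for the spectral baseline")
        return self._logreg.predict_proba(self._scaler.transform(features))

    def predict_proba(self, trials: np.ndarray) -> np.ndarray:
        """Class probabilities, columns ordered (control, patient)."""
        trials = self._check_shape(trials)
        if self.config.family == "spectral_baseline":
            return self.predict_proba_from_features(self._extractor(trials))
        x = self._net_input(trials)
        out = np.empty((trials.shape[0], 2))
        for start in range(0, trials.shape[0], 256):
            logits = self._net.forward(x[start:start + 256], train=False)
            out[start:start + 256] = _nn.softmax(logits)
        return out

    def predict(self, trials: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(probabilities, hard labels); probability ties go to patient."""
        proba = self.predict_proba(trials)
        labels = np.where(proba[:, 1] >= 0.5, PATIENT, CONTROL)
        return proba, labels

    def penultimate_features(self, trials: np.ndarray) -> np.ndarray:
        """Flattened representation feeding the final classification layer
        (the last convolutional block for the compact CNN, the last hidden
        dense layer for the deep CNN, band powers for the baseline)."""
        trials = self._check_shape(trials)
        if self.config.family == "spectral_baseline":
            return self._scaler.transform(self._extractor(trials))
        x = self._net_input(trials)
        parts = []
        for start in range(0, trials.shape[0], 256):
            parts.append(self._net.forward(x[start:start + 256], train=False,
                                           upto=self._penultimate_idx))
        return np.concatenate(parts)


def _encode_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ConfigurationError(
            f"training data contains a single class ({classes.tolist()}); "
            "need both patient and control trials"
        )
    return (y == PATIENT).astype(int)


def baseline_features(trials: np.ndarray, fs_hz: float) -> np.ndarray:
    """Band-power feature matrix of the spectral baseline (deterministic);
    precompute once per trial set to avoid re-running Welch per CV fold."""
    return _BandPowerExtractor(fs_hz)(np.asarray(trials))


def train(trials: np.ndarray, labels: np.ndarray, config: ModelConfig,
          fs_hz: float, features: Optional[np.ndarray] = None) -> TrainedModel:
    """Fit one model on (trials, labels); pure function of (data, config.seed).

    ``features`` optionally supplies precomputed :func:`baseline_features`
    rows for the spectral baseline (ignored by the CNN families).
    """
    trials = np.asarray(trials)
    if trials.ndim != 3:
        raise ConfigurationError("trials must be [n_trials, n_channels, n_samples]")
    if not np.all(np.isfinite(trials)):
        raise ConfigurationError("trials contain non-finite values")
    y = _encode_labels(labels)
    n, c, t = trials.shape

    if config.family == "spectral_baseline":
        extractor = _BandPowerExtractor(fs_hz)
        feats = extractor(trials) if features is None else np.asarray(features)
        scaler = StandardScaler().fit(feats)
        clf = LogisticRegression(C=100.0, max_iter=2000)
        clf.fit(scaler.transform(feats), y)
        return TrainedModel(config=config, input_shape=(c, t),
                            feature_dim=feats.shape[1], fs_hz=fs_hz,
                            _extractor=extractor, _scaler=scaler, _logreg=clf)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if config.family == "compact_cnn":
        net, feature_dim, pen_idx = _compact_net(c, t, fs_hz, config, rng)
        x = _zscore(trials)[:, None, :, :]
    else:
        # deep net consumes channels as feature maps: (N, C, 1, T)
        net, feature_dim, pen_idx = _deep_net(c, t, config, rng)
        x = _zscore(trials)[:, :, None, :]
    opt = _nn.Adam(net.parameters(), lr=config.learning_rate)
    idx = np.arange(n)
    for epoch in range(config.epochs):
        rng.shuffle(idx)
        for start in range(0, n, config.batch_size):
            b = idx[start:start + config.batch_size]
            logits = net.forward(x[b], train=True)
            loss, dlogits = _nn.cross_entropy_grad(logits, y[b])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // config.batch_size} "
                    f"(family={config.family}, lr={config.learning_rate}); aborting"
                )
            net.backward(dlogits)
            opt.step()
    model = TrainedModel(config=config, input_shape=(c, t), feature_dim=feature_dim,
                         fs_hz=fs_hz, _net=net, _penultimate_idx=pen_idx)
    return model


def train_trialset(trialset: TrialSet, config: ModelConfig,
                   idx: Optional[np.ndarray] = None) -> TrainedModel:
    """Convenience wrapper training on (a subset of) a TrialSet."""
    if idx is None:
        idx = np.arange(trialset.n_trials)
    return train(trialset.trials[idx], trialset.labels[idx], config, trialset.fs_hz)


def predict(model: TrainedModel, trials: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return model.predict(trials)


def penultimate_features(model: TrainedModel, trials: np.ndarray) -> np.ndarray:
    return model.penultimate_features(trials)
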
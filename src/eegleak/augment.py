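"""Downsampling and cropping-based data augmentation.

A continuous epoch is cropped into fixed-length windows ("trials"), either
non-overlapping or with 75% overlap.  Crop starts are ``0, step, 2*step, …``
with ``step = window_s * (1 - overlap_fraction)``, giving
``floor((T - w) / step) + 1`` trials per recording.  Each trial keeps full
provenance (subject, label, crop offset) so cross-validation plans can be
audited for subject contamination downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .cohort import EEGRecording
from .errors import ConfigurationError

#: window lengths (seconds) used in the experimental grid
DEFAULT_WINDOWS_S = (5.0, 10.0, 15.0, 20.0, 60.0)

NON_OVERLAP = 0.0
OVERLAP_75 = 0.75


@dataclass(frozen=True)
class AugmentationParams:
    """Cropping parameters: window length and fractional overlap."""

    window_s: float
    overlap_fraction: float = NON_OVERLAP

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ConfigurationError(f"window_s must be > 0, got {self.window_s}")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ConfigurationError(
                f"overlap_fraction must be in [0, 1), got {self.overlap_fraction}"
            )

    @property
    def step_s(self) -> float:
        return self.window_s * (1.0 - self.overlap_fraction)


@dataclass
class TrialSet:
    """Cropped trials with per-trial provenance."""

    trials: np.ndarray = field(repr=False)  # [n_trials, n_channels, window_samples]
    subject_ids: np.ndarray  # [n_trials] str
    labels: np.ndarray  # [n_trials] str
    crop_start_s: np.ndarray  # [n_trials] float
    params: AugmentationParams
    fs_hz: float

    def __len__(self) -> int:
        return self.trials.shape[0]

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def window_samples(self) -> int:
        return self.trials.shape[2]

    def manifest(self) -> pd.DataFrame:
        """Audit table: one row per trial with its provenance."""
        return pd.DataFrame({
            "trial": np.arange(self.n_trials),
            "subject_id": self.subject_ids,
            "label": self.labels,
            "crop_start_s": self.crop_start_s,
        })

    def save_manifest(self, path: str | Path) -> Path:
        path = Path(path)
        self.manifest().to_csv(path, index=False)
        return path

    def subset(self, idx: np.ndarray) -> "TrialSet":
        return TrialSet(self.trials[idx], self.subject_ids[idx], self.labels[idx],
                        self.crop_start_s[idx], self.params, self.fs_hz)


def downsample(recording: EEGRecording, target_fs: float) -> EEGRecording:
    """Anti-aliased resampling to ``target_fs`` (no upsampling allowed).

    Uses polyphase FIR resampling, which low-pass filters below the new
    Nyquist frequency before decimating.
    """
    if target_fs > recording.fs_hz:
        raise ConfigurationError(
            f"target_fs ({target_fs}) exceeds recording fs ({recording.fs_hz}); "
            "upsampling is not supported"
        )
    if target_fs == recording.fs_hz:
        return EEGRecording(recording.subject_id, recording.label,
                            recording.signal.copy(), recording.fs_hz)
    ratio = Fraction(target_fs / recording.fs_hz).limit_denominator(10_000)
    sig = resample_poly(recording.signal, ratio.numerator, ratio.denominator, axis=1)
    return EEGRecording(recording.subject_id, recording.label, sig, target_fs)


def count_crops(duration_s: float, window_s: float, overlap_fraction: float = 0.0) -> int:
    """Number of crops of length ``window_s`` that fit in ``duration_s``.

    ``floor((T - w) / step) + 1`` with ``step = w * (1 - overlap)``.
    """
    params = AugmentationParams(window_s, overlap_fraction)
    if window_s > duration_s:
        raise ConfigurationError(
            f"window_s ({window_s}) exceeds recording duration ({duration_s})"
        )
    # guard against float fuzz at exact multiples, e.g. (60 - 10) / 2.5
    return int(np.floor((duration_s - window_s) / params.step_s + 1e-9)) + 1


def crop(recording: EEGRecording, params: AugmentationParams) -> TrialSet:
    """Crop one recording into a TrialSet with provenance filled in."""
    n = count_crops(recording.duration_s, params.window_s, params.overlap_fraction)
    wlen = int(round(params.window_s * recording.fs_hz))
    step = int(round(params.step_s * recording.fs_hz))
    if step <= 0:
        raise ConfigurationError("crop step must be at least one sample")
    starts = np.arange(n) * step
    trials = np.stack([recording.signal[:, s:s + wlen] for s in starts])
    return TrialSet(
        trials=trials,
        subject_ids=np.array([recording.subject_id] * n),
        labels=np.array([recording.label] * n),
        crop_start_s=starts / recording.fs_hz,
        params=params,
        fs_hz=recording.fs_hz,
    )


def build_trialset(recordings: list[EEGRecording], params: AugmentationParams) -> TrialSet:
    """Concatenate per-recording crops, preserving recording order."""
    if not recordings:
        return TrialSet(
            trials=np.zeros((0, 0, 0)),
            subject_ids=np.array([], dtype=str),
            labels=np.array([], dtype=str),
            crop_start_s=np.array([], dtype=float),
            params=params,
            fs_hz=0.0,
        )
    parts = [crop(r, params) for r in recordings]
    return TrialSet(
        trials=np.concatenate([p.trials for p in parts]),
        subject_ids=np.concatenate([p.subject_ids for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        crop_start_s=np.concatenate([p.crop_start_s for p in parts]),
        params=params,
        fs_hz=recordings[0].fs_hz,
    )
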
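"""Synthetic resting-state EEG cohorts with subject fingerprints.

The generator produces a two-group cohort (patients vs controls) of
continuous multichannel epochs whose statistical structure mirrors what
makes cropping-based augmentation leak information between training and
test data:

* every subject carries a stable *spectral fingerprint* — per-band,
  per-channel log-power offsets drawn once per subject and held fixed for
  the whole epoch, so any two crops of the same recording resemble each
  other more than crops from different subjects;
* patients optionally carry a *group effect* — a standardized shift of
  target-band log-power on a fixed subset of channels — which is the only
  label-linked signal in the data.

Signals are a 1/f-shaped broadband background plus band-limited
oscillations in the conventional EEG bands (delta 1–4, theta 4–8,
alpha 8–12, beta 13–30 Hz) plus white sensor noise, stationary within the
epoch.  Everything is a pure function of ``CohortSpec.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .errors import ConfigurationError, FormatError

PATIENT = "patient"
CONTROL = "control"

#: conventional EEG band edges in Hz
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
}

#: per-band RMS amplitude of the band-limited oscillation, arbitrary units.
#: Chosen so the oscillations dominate the in-band power over the white
#: noise floor, keeping log-power shifts approximately additive.
BAND_AMPLITUDE: dict[str, float] = {
    "delta": 2.0,
    "theta": 1.5,
    "alpha": 2.0,
    "beta": 1.0,
}

BACKGROUND_AMPLITUDE = 1.0  # RMS of the 1/f background

_SCHEMA_VERSION = "eegleak-cohort-1"


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    The cohort sizes default to 77 patients and 58 controls; all other
    fields are generator knobs with no empirical counterpart and are
    documented in docs/methods.md.
    """

    n_patients: int = 77
    n_controls: int = 58
    n_channels: int = 64
    duration_s: float = 60.0
    fs_hz: float = 200.0
    fingerprint_strength: float = 0.5
    effect_size: float = 0.8
    target_band: tuple[float, float] = (8.0, 12.0)
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_controls", "n_channels"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ConfigurationError(f"{name} must be an integer >= 1, got {v!r}")
        if self.duration_s <= 0:
            raise ConfigurationError(f"duration_s must be > 0, got {self.duration_s}")
        if self.fs_hz <= 0:
            raise ConfigurationError(f"fs_hz must be > 0, got {self.fs_hz}")
        n = self.duration_s * self.fs_hz
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"duration_s * fs_hz must be an integer number of samples, got {n}"
            )
        if self.fingerprint_strength < 0:
            raise ConfigurationError(
                f"fingerprint_strength must be >= 0, got {self.fingerprint_strength}"
            )
        lo, hi = self.target_band
        if not (0 < lo < hi):
            raise ConfigurationError(f"target_band must satisfy 0 < lo < hi, got {self.target_band}")
        if self.fs_hz <= 2 * hi:
            raise ConfigurationError(
                f"fs_hz must exceed twice the upper edge of target_band "
                f"({self.fs_hz} <= 2 * {hi})"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["target_band"] = list(d["target_band"])
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "CohortSpec":
        d = json.loads(s)
        d["target_band"] = tuple(d["target_band"])
        return cls(**d)


@dataclass
class EEGRecording:
    """One subject's continuous multichannel epoch with its diagnosis label."""

    subject_id: str
    label: str  # PATIENT or CONTROL
    signal: np.ndarray = field(repr=False)  # [n_channels, n_samples]
    fs_hz: float

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ConfigurationError("signal must be a 2-D [channels, samples] array")
        if not np.all(np.isfinite(self.signal)):
            raise ConfigurationError("signal contains non-finite values")
        if self.label not in (PATIENT, CONTROL):
            raise ConfigurationError(f"label must be '{PATIENT}' or '{CONTROL}', got {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


def _band_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, lo: float, hi: float) -> np.ndarray:
    """Band-limited unit-RMS Gaussian noise, synthesised in the frequency domain."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = (freqs >= lo) & (freqs <= hi)
    spec = np.zeros((n_channels, freqs.size), dtype=np.complex128)
    m = int(mask.sum())
    if m == 0:
        return np.zeros((n_channels, n_samples))
    spec[:, mask] = rng.standard_normal((n_channels, m)) + 1j * rng.standard_normal((n_channels, m))
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def _pink_background(rng: np.random.Generator, n_channels: int, n_samples: int,
                     fs: float) -> np.ndarray:
    """1/f-shaped background (power ∝ 1/f above 1 Hz), unit RMS per channel."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], 1.0))
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * shape
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def effect_channels(spec: CohortSpec) -> np.ndarray:
    """Channel subset carrying the group effect: one quarter of channels,
    chosen reproducibly from the cohort seed."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xEFFEC]))
    k = max(1, spec.n_channels // 4)
    return np.sort(rng.choice(spec.n_channels, size=k, replace=False))


def generate_cohort(spec: CohortSpec) -> list[EEGRecording]:
    """Generate the full cohort; a pure function of ``spec`` (incl. seed).

    Patients are listed first (``P001``…), controls after (``C001``…).
    """
    n_samples = spec.n_samples
    eff_ch = effect_channels(spec)
    # per-subject child seeds, independent of cohort composition order
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_subjects)
    recs: list[EEGRecording] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        is_patient = i < spec.n_patients
        label = PATIENT if is_patient else CONTROL
        sid = f"P{i + 1:03d}" if is_patient else f"C{i - spec.n_patients + 1:03d}"

        x = BACKGROUND_AMPLITUDE * _pink_background(rng, spec.n_channels, n_samples, spec.fs_hz)
        # per-subject fingerprint: log-power offsets, fixed for the epoch
        for band, (lo, hi) in BANDS.items():
            g = rng.normal(0.0, spec.fingerprint_strength, size=spec.n_channels)
            amp = BAND_AMPLITUDE[band] * np.exp(g / 2.0)[:, None]
            if is_patient and spec.effect_size != 0.0 and _band_overlaps(
                    (lo, hi), spec.target_band):
                # shift of effect_size standardized units (units of the
                # between-subject log-power sd = fingerprint_strength)
                shift = spec.effect_size * spec.fingerprint_strength
                mult = np.ones(spec.n_channels)
                mult[eff_ch] = np.exp(shift / 2.0)
                amp = amp * mult[:, None]
            x += amp * _band_noise(rng, spec.n_channels, n_samples, spec.fs_hz, lo, hi)
        if spec.noise_sd > 0:
            x += rng.normal(0.0, spec.noise_sd, size=x.shape)
        recs.append(EEGRecording(subject_id=sid, label=label, signal=x, fs_hz=spec.fs_hz))
    return recs


def _band_overlaps(band: tuple[float, float], target: tuple[float, float]) -> bool:
    return band[0] < target[1] and target[0] < band[1]


def save_cohort(recordings: list[EEGRecording], path: str | Path,
                spec: CohortSpec | None = None) -> Path:
    """Write a cohort to a single HDF5 container (lossless round-trip)."""
    path = Path(path)
    if not recordings:
        raise ConfigurationError("cannot save an empty cohort")
    fs = recordings[0].fs_hz
    n_ch = recordings[0].n_channels
    n_s = recordings[0].n_samples
    sig = np.stack([r.signal for r in recordings])
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = _SCHEMA_VERSION
        f.attrs["fs_hz"] = fs
        if spec is not None:
            f.attrs["spec_json"] = spec.to_json()
            f.attrs["seed"] = spec.seed
        f.create_dataset("signals", data=sig, shape=(len(recordings), n_ch, n_s))
        str_dt = h5py.string_dtype()
        f.create_dataset("subject_ids", data=[r.subject_id for r in recordings], dtype=str_dt)
        f.create_dataset("labels", data=[r.label for r in recordings], dtype=str_dt)
    return path


def load_cohort(path: str | Path) -> list[EEGRecording]:
    """Read a cohort container written by :func:`save_cohort`."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            version = f.attrs.get("schema_version")
            if version != _SCHEMA_VERSION:
                raise FormatError(
                    f"{path}: unknown cohort schema {version!r} (expected {_SCHEMA_VERSION!r})"
                )
            for key in ("signals", "subject_ids", "labels"):
                if key not in f:
                    raise FormatError(f"{path}: missing dataset {key!r}")
            fs = float(f.attrs["fs_hz"])
            sig = f["signals"][...]
            sids = [s.decode() if isinstance(s, bytes) else s for s in f["subject_ids"][...]]
            labels = [s.decode() if isinstance(s, bytes) else s for s in f["labels"][...]]
    except OSError as e:  # h5py raises OSError on corrupt/truncated files
        raise FormatError(f"{path}: not a readable cohort container ({e})") from e
    if not (len(sids) == len(labels) == sig.shape[0]):
        raise FormatError(f"{path}: inconsistent record counts")
    return [EEGRecording(subject_id=s, label=l, signal=sig[i], fs_hz=fs)
            for i, (s, l) in enumerate(zip(sids, labels))]


def load_cohort_spec(path: str | Path) -> CohortSpec | None:
    """Recover the generating spec stored in a cohort container, if present."""
    with h5py.File(path, "r") as f:
        s = f.attrs.get("spec_json")
    return CohortSpec.from_json(s) if s is not None else None
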
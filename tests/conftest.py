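"""Shared fixtures: small synthetic cohorts sized for CPU test runs."""

import numpy as np
import pytest

import eegleak as el


@pytest.fixture(scope="session")
def separable_trialset():
    """Strongly separable cohort (large group effect, little noise):
    any sane classifier should fit its training set almost perfectly."""
    spec = el.CohortSpec(n_patients=10, n_controls=10, n_channels=8,
                         duration_s=30, fs_hz=64, fingerprint_strength=0.5,
                         effect_size=6.0, noise_sd=0.05, seed=3)
    recs = el.generate_cohort(spec)
    return el.build_trialset(recs, el.AugmentationParams(5.0, 0.0))


@pytest.fixture(scope="session")
def fingerprint_cohort():
    """Pure-leakage cohort: strong subject fingerprints, zero group effect."""
    spec = el.CohortSpec(n_patients=12, n_controls=12, n_channels=8,
                         duration_s=60, fs_hz=64, fingerprint_strength=1.0,
                         effect_size=0.0, noise_sd=0.3, seed=7)
    return spec, el.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Small mixed cohort with a moderate effect for pipeline-level tests."""
    spec = el.CohortSpec(n_patients=8, n_controls=8, n_channels=4,
                         duration_s=30, fs_hz=64, fingerprint_strength=0.8,
                         effect_size=1.5, noise_sd=0.5, seed=2)
    return spec, el.generate_cohort(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
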
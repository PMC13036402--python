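"""Shared fixtures: deterministic synthetic signals and cohorts."""

import numpy as np
import pytest

import pulsewave as pw


@pytest.fixture(scope="session")
def clean_params():
    """Noise- and drift-free beat model at 60 Hz."""
    return pw.BeatModelParams(noise_snr_db=None, drift_amp=0.0, fs=60.0, seed=1)


@pytest.fixture(scope="session")
def clean_train(clean_params):
    """16 s clean beat train plus its ground-truth manifest."""
    return pw.generate_beat_train(clean_params, duration_s=16.0)


@pytest.fixture(scope="session")
def clean_beats(clean_train):
    sig, _ = clean_train
    return pw.segment_signal(sig)


@pytest.fixture(scope="session")
def default_record():
    """Extracted sample record under default (noisy, drifting) conditions."""
    sig, truth = pw.generate_beat_train(pw.BeatModelParams(seed=7), duration_s=35.0)
    rec = pw.extract_sample_record(sig, "P000", "P000-S0")
    return rec, truth


@pytest.fixture(scope="session")
def parametric_cohort():
    """Small parametric cohort with a known effect on crest time."""
    cp = pw.CohortParams(
        n_participants=40,
        samples_per_participant=4,
        effect_map={"phq9": {"ct": 80.0}},
        noise_sd=2.0,
        seed=11,
    )
    return pw.generate_cohort(cp)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
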
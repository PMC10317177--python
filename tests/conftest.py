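"""Shared fixtures: synthetic cohorts generated once per session."""

import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from swsync.config import RunConfig
from swsync.model import AbsenceDetector
from swsync.simulate import SimConfig, gen_cohort

#: master seed for all session fixtures
SEED = 2023


@pytest.fixture(scope="session")
def study_config() -> SimConfig:
    """The study conditions: 10 subjects, 6 seizures each, SWD amplitude 4x
    background, 0.3-rad cross-channel phase jitter."""
    return SimConfig(seed=SEED)


@pytest.fixture(scope="session")
def study_cohort(study_config):
    return gen_cohort(study_config)


@pytest.fixture(scope="session")
def study_model(study_cohort) -> AbsenceDetector:
    recordings = [rec for rec, _ in study_cohort]
    annotations = {
        rec.subject_id: truth.to_annotations(rec.subject_id)
        for rec, truth in study_cohort
    }
    return AbsenceDetector.from_recordings(
        recordings, annotations, RunConfig(seed=SEED)
    )


@pytest.fixture(scope="session")
def study_results(study_model):
    return study_model.fit(postprocess=True)


@pytest.fixture(scope="session")
def small_cohort():
    """A faster 4-subject cohort for tests that only need plausible features."""
    cfg = SimConfig(n_subjects=4, duration_s=300.0, n_seizures=4, seed=SEED + 1)
    return gen_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort) -> pd.DataFrame:
    from swsync.segmentation import extract_features

    frames = [
        extract_features(rec, truth.to_annotations(rec.subject_id), RunConfig())
        for rec, truth in small_cohort
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)
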
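"""Shared fixtures: small cohorts and the expensive trained-study fixtures.

The two full-pipeline studies (trait-only and planted-state cohorts) are
session-scoped because several tests interrogate different aspects of the
same runs.
"""

import numpy as np
import pytest

from eegage import (CohortConfig, ModelConfig, StudyConfig, TrainConfig,
                    generate_cohort, run_study)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Signal-bearing cohort small enough for structural tests."""
    cfg = CohortConfig(n_subjects=12, duration_s=30.0, sfreq=100.0,
                       recordings_per_subject_mean=2.0,
                       transition_fraction=0.2, seed=42)
    recordings, latents = generate_cohort(cfg)
    return cfg, recordings, latents


def _desk_model() -> ModelConfig:
    return ModelConfig(n_channels=8, n_blocks=4, kernel_size=5,
                       n_filters=32, dropout=0.1)


def _desk_train(epochs: int = 12) -> TrainConfig:
    return TrainConfig(epochs=epochs, batch_size=128, crops_per_recording=24,
                       lr=2e-3, seed=0)


@pytest.fixture(scope="session")
def study_trait():
    """Full pipeline on a trait-only cohort (stable per-subject offsets,
    no pathology-linked gap shift)."""
    cfg = StudyConfig(
        cohort=CohortConfig(n_subjects=110, duration_s=60.0, trait_sd=4.0,
                            state_effect=0.0, pathology_fraction=0.35,
                            transition_fraction=0.18, seed=101),
        model=_desk_model(), train=_desk_train(), cv_folds=3, fe_runs=2,
        n_permutations=2000, seed=7)
    return run_study(cfg)


@pytest.fixture(scope="session")
def study_state():
    """Full pipeline on a cohort with a planted pathology-linked (state)
    gap shift of 10 years and a small trait component."""
    cfg = StudyConfig(
        cohort=CohortConfig(n_subjects=100, duration_s=60.0, trait_sd=1.0,
                            state_effect=10.0, pathology_fraction=0.35,
                            transition_fraction=0.3, seed=202),
        model=_desk_model(), train=_desk_train(), cv_folds=3, fe_runs=2,
        n_permutations=2000, seed=9)
    return run_study(cfg)
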
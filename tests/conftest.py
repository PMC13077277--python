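"""Shared fixtures: session-scoped synthetic data so the suite stays fast."""

import numpy as np
import pytest

from gaitpipe.model_eval import CVPlan, run_topk_sweep
from gaitpipe.pipeline import build_feature_table, outcome_labels, split_feature_table
from gaitpipe.synthetic_gait import (
    EffectConfig,
    NoiseConfig,
    generate_walk,
    sample_cohort,
    sample_subject,
)


@pytest.fixture(scope="session")
def subject():
    return sample_subject("female", "under65", EffectConfig(), rng_seed=1)


@pytest.fixture(scope="session")
def clean_walk(subject):
    """A 4-stride walk with no landmark jitter (closed-form timing)."""
    return generate_walk(subject, n_strides=4, frame_rate_hz=30.0,
                         noise=NoiseConfig(jitter_sd_px=0.0), rng_seed=2)


@pytest.fixture(scope="session")
def small_cohort():
    """60 recordings at default effects and jitter, no failures."""
    return sample_cohort(60, rng_seed=5, noise=NoiseConfig(jitter_sd_px=2.0))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    table, segments = build_feature_table(small_cohort)
    return table, segments


@pytest.fixture(scope="session")
def small_sweep(small_table):
    """A small but complete sweep on the 60-recording cohort, sex outcome."""
    table, _ = small_table
    X, _ = split_feature_table(table)
    y = outcome_labels(table, "sex")
    plan = CVPlan(n_folds=5, n_repetitions=4, base_seed=3)
    return run_topk_sweep(X, y, [1, 5, 15], plan), X, y, plan


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
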
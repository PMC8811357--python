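"""Shared fixtures: small phantom cohorts and a trained voxel classifier.

Everything is generated programmatically and seeded; the session-scoped
model is shared across tests to keep the suite fast.
"""

import numpy as np
import pytest

from cmbselect.config import PipelineConfig
from cmbselect.phantom import PhantomSpec, generate_cohort, generate_phantom
from cmbselect.pipeline import run_predict, run_train


SMALL_GRID = (64, 64, 16)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(grid_shape=SMALL_GRID)


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig(seed=11)


@pytest.fixture(scope="session")
def phantom_subject(small_spec):
    """One positive subject with CMBs, vessels and sulci."""
    from dataclasses import replace

    return generate_phantom(replace(small_spec, n_cmbs=4, seed=42))


@pytest.fixture(scope="session")
def small_model(small_spec, cfg):
    train_cohort = generate_cohort(6, 1.0, small_spec, seed=301)
    return run_train(train_cohort, cfg)


@pytest.fixture(scope="session")
def small_test_cohort(small_spec):
    return generate_cohort(8, 0.5, small_spec, seed=302)


@pytest.fixture(scope="session")
def small_results(small_model, small_test_cohort, cfg):
    """Full pipeline results for the small test cohort (Th_NCMB = 1)."""
    cfg1 = cfg.with_th_ncmb(1)
    return [
        run_predict(s.image, s.brain_mask, small_model, cfg1,
                    subject_id=s.subject_id, index=i)
        for i, s in enumerate(small_test_cohort)
    ]
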
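"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from cogspace import pipeline, synthgen


@pytest.fixture(scope="session")
def paper_design():
    """Design with the full-study sampling geometry (103 tasks, 12+6 runs)."""
    return synthgen.make_design(
        103, 12, 6, 556, (6, 8), tr=2, seed=1, test_block_s=824
    )


@pytest.fixture(scope="session")
def cohort_small():
    """Three-subject cohort, small enough for repeated full fits."""
    return synthgen.make_cohort(
        3,
        n_tasks=12,
        n_clusters=3,
        n_terms=24,
        n_voxels=300,
        n_train_runs=2,
        n_test_runs=2,
        run_duration_s=240,
        sigma=1.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def fits_small(cohort_small):
    return pipeline.fit_cohort(cohort_small, "tasktype")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
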
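"""Shared fixtures: hand-built tiny datasets and session-scoped
study-like synthetic data plus one scaled MCMC fit reused by several
tests."""

from __future__ import annotations

import numpy as np
import pytest

from taskrt import joint_model as jm
from taskrt.data_model import ItemMeta, TaskDataset
from taskrt.synthetic import generate, study_like_config


@pytest.fixture
def tiny_dataset() -> TaskDataset:
    """4 persons x 2 items with easily hand-checked summaries."""
    Y = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
    T = np.array([[60.0, 120.0], [30.0, 40.0], [10.0, 20.0], [5.0, 15.0]])
    items = [
        ItemMeta(1, "MC", "single-selection", 0.25),
        ItemMeta(2, "CR", "explanation", 0.0),
    ]
    return TaskDataset(Y=Y, T=T, items=items, person_ids=["p1", "p2", "p3", "p4"])


@pytest.fixture(scope="session")
def study_data():
    """Study-like synthetic dataset (with covariates) plus its truth."""
    return generate(study_like_config(seed=11))


@pytest.fixture(scope="session")
def scaled_fit():
    """One scaled MCMC fit of the study-like preset.

    J=445, I=11, fixed published item parameters; 2 chains of 5,000
    iterations with 2,000 burn-in and thinning 5.  Session-scoped
    because several convergence/recovery checks share it.
    """
    dataset, truth = generate(study_like_config(seed=5, covariates=False))
    config = jm.McmcConfig(
        chains=2, iterations=5_000, burn_in=2_000, thin=5, seed=9
    )
    draws = jm.sample_posterior(dataset, config)
    return dataset, truth, draws
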
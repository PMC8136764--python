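"""Shared fixtures: synthetic datasets are generated once per session."""

import numpy as np
import pytest
from hypothesis import settings

from remstage.features import FeatureMatrix, extract_matrix
from remstage.synthetic import generate_stage_epochs

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")

#: Root seed of the synthetic study conditions used across the suite.
STUDY_SEED = 1234


@pytest.fixture(scope="session")
def recovery_grid():
    """1000 balanced epochs (200 per stage) with separated stage profiles."""
    return generate_stage_epochs(epochs_per_stage=200, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def recovery_features(recovery_grid) -> FeatureMatrix:
    return extract_matrix(recovery_grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(STUDY_SEED)
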
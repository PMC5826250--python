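"""Shared fixtures: small synthetic datasets generated at test time."""

import warnings

import numpy as np
import pytest
from hypothesis import settings

from numtuning import ConditionLabel, GeneratorConfig, PatternSet
from numtuning.simulate import generate_behavior, generate_psc

warnings.filterwarnings("ignore", category=FutureWarning)

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    """A cheap generator configuration for end-to-end tests."""
    return GeneratorConfig(
        n_subjects=2, n_voxels=30, exemplars_per_condition=4, seed=7
    )


@pytest.fixture(scope="session")
def psc_default():
    """One PSC dataset at the default (full-scale) study conditions."""
    return generate_psc(GeneratorConfig(), seed=11)


@pytest.fixture(scope="session")
def trials_default():
    """One behavioral dataset at the default study conditions."""
    return generate_behavior(GeneratorConfig(), seed=11)


def gaussian_pattern_pair(seed=0, n_exemplars=50, n_voxels=100, separation=0.0):
    """Two PatternSets from Gaussians with mean separation in noise-SD units."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n_exemplars, n_voxels))
    b = rng.normal(separation, 1.0, (n_exemplars, n_voxels))
    return (
        PatternSet("s01", ConditionLabel("random", 2), a),
        PatternSet("s01", ConditionLabel("random", 5), b),
    )
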
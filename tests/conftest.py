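"""Shared fixtures: the reference synthetic population and a fitted model."""

import numpy as np
import pytest

from screenrhythms import GeneratorConfig, RhythmNMF
from screenrhythms.simulate import counts_to_profiles, generate_hourly_counts


@pytest.fixture(scope="session")
def default_population():
    """Hourly count grid + ground truth of the default 200-person cohort."""
    return generate_hourly_counts(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def default_profiles(default_population):
    counts, gt = default_population
    return counts_to_profiles(counts, gt.participant_ids)


@pytest.fixture(scope="session")
def fitted4(default_profiles):
    """Multi-restart K=4 factorization of the default cohort."""
    return RhythmNMF(default_profiles, 4).fit_multistart(n_restarts=20, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
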
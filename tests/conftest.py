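"""Shared fixtures: small synthetic datasets and reduced sampler settings.

Expensive hierarchical fits are session-scoped so several tests can share
them; all randomness is seeded.
"""

import warnings
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from wmbind.generate import GroundTruth, simulate_dataset
from wmbind.hierarchical import MCMCConfig
from wmbind.mmm import MMMParams
from wmbind.mpt import MPTParams

warnings.filterwarnings("ignore", category=FutureWarning)

# property tests are deterministic: same examples every run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

FIXTURE_CSV = Path(__file__).parent / "data" / "fixture_trials.csv"


@pytest.fixture(scope="session")
def small_mcmc() -> MCMCConfig:
    """Reduced sampler settings for unit-level fits (not for inference claims)."""
    return MCMCConfig(chains=2, warmup=600, draws=600, seed=314)


@pytest.fixture(scope="session")
def mpt_truth() -> GroundTruth:
    """Binding declines with set size; item memory does not."""
    return GroundTruth(group=MPTParams(0.6, -0.35, 2.0, 0.0), n_subjects=8, seed=101)


@pytest.fixture(scope="session")
def mpt_trials_small(mpt_truth):
    return simulate_dataset(mpt_truth, words=False)


@pytest.fixture(scope="session")
def mmm_truth() -> GroundTruth:
    return GroundTruth(
        group=MMMParams(log_b=np.log(0.3), a_intercept=np.log(4.0), a_slope=0.0,
                        c_intercept=10.0, c_slope=-2.0),
        n_subjects=8, seed=202,
    )


@pytest.fixture(scope="session")
def mmm_trials_small(mmm_truth):
    return simulate_dataset(mmm_truth, words=False)


@pytest.fixture(scope="session")
def mpt_fit_small(mpt_trials_small, small_mcmc):
    from wmbind.mpt import fit_mpt

    return fit_mpt(mpt_trials_small, small_mcmc)
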
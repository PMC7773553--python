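import numpy as np
import pytest

from wormdecode.config import (
    EnvironmentCondition,
    Genotype,
    McmcSettings,
    OptimizerSettings,
    StudyConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def single_condition():
    return EnvironmentCondition(food=2e7, temperature=20.0)


@pytest.fixture
def small_grid():
    return [
        EnvironmentCondition(food=f, temperature=t)
        for t in (15.0, 25.0)
        for f in (0.0, 2e7, 6e8)
    ]


@pytest.fixture
def wt_study(single_condition):
    """One condition, wild type only, no batch noise, generous schedule."""
    return StudyConfig(
        conditions=[single_condition],
        genotypes=[Genotype.wild_type],
        n_animals_per_cell=500,
        n_batches=1,
        batch_sd_log_scale=0.0,
        batch_sd_log_shape=0.0,
        censoring_day_schedule=[60.0],
        record_whole_days=False,
        seed=7,
    )


@pytest.fixture
def fast_mcmc():
    return McmcSettings(n_iter=800, seed=3)


@pytest.fixture
def fast_opt():
    return OptimizerSettings(n_restarts=10, n_iter=300, seed=5)
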
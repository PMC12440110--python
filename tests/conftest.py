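import numpy as np
import pytest

from mesoinfluence import bandit, synthetic


@pytest.fixture(scope="session")
def task_cfg():
    return bandit.TaskConfig(seed=0)


@pytest.fixture(scope="session")
def default_session(task_cfg):
    return bandit.generate_schedule(task_cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects, tiny panels: enough for integration tests, fast."""
    cohort, panel, records, truth = synthetic.simulate_cohort(
        synthetic.NetSimConfig(n_timepoints=120),
        bandit.TaskConfig(),
        synthetic.PopulationSpec(),
        6,
        seed=123,
    )
    return cohort, panel, records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
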
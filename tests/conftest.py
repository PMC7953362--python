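import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hsroc import FixedTarget, MCMCConfig, example_dataset, run_mcmc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    """The packaged 9-study example dataset."""
    return example_dataset()


@pytest.fixture(scope="session")
def small_fit(table1):
    """A quick (non-converged-quality) fit with derived quantities, for
    plumbing tests that only need structurally valid draws."""
    target = FixedTarget("spec", 0.8)
    config = MCMCConfig(chains=2, iter=200, warmup=100, seed=3)
    return run_mcmc(table1, config, target=target), target


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
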
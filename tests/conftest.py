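import numpy as np
import pytest

from phagecycle.config import load_example_config
from phagecycle.economics import economics_summary
from phagecycle.kinetics import (
    KineticParameters,
    build_discretization,
    reference_infection_response,
)
from phagecycle.process import simulate_process


@pytest.fixture(scope="session")
def params():
    """Reference E. coli growth parameterization with zero decay."""
    return KineticParameters()


@pytest.fixture(scope="session")
def response():
    return reference_infection_response()


@pytest.fixture(scope="session")
def disc(response):
    return build_discretization(response, M=10, N=50)


@pytest.fixture(scope="session")
def small_disc(response):
    """Coarse discretization for fast process-level tests."""
    return build_discretization(response, M=3, N=10)


@pytest.fixture(scope="session")
def optimal_config():
    return load_example_config("optimal_50L")


@pytest.fixture(scope="session")
def optimal_run(optimal_config):
    """The 45-cycle simulation of the optimized 50 L scenario (shared:
    several tests interrogate different aspects of the same run)."""
    cfg = optimal_config
    return simulate_process(cfg.process, cfg.params, cfg.disc)


@pytest.fixture(scope="session")
def optimal_economics(optimal_config, optimal_run):
    cfg = optimal_config
    return economics_summary(optimal_run.records, cfg.process, cfg.costs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
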
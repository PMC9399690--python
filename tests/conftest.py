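import numpy as np
import pytest

from cartsim import GEN1, GEN2, assemble_model, default_registry
from cartsim.simulate import SimulationSettings


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def gen1_network(registry):
    return assemble_model(GEN1, registry)


@pytest.fixture(scope="session")
def gen2_network(registry):
    return assemble_model(GEN2, registry)


@pytest.fixture(scope="session")
def settings():
    return SimulationSettings()


@pytest.fixture(scope="session")
def lambda_path(registry):
    """Shared selection path (reduced swarm budget) for the optimizer and
    resimulation checks; computed once per session."""
    from cartsim.optimize import FAST_SWARM, OptimizationProblem, lambda_sweep

    problem = OptimizationProblem(swarm=FAST_SWARM, seed=3)
    return lambda_sweep(registry, problem=problem)
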
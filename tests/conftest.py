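import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from gatkin import (CellParams, ChargeMovementParams, NoiseSpec, SolutionCondition,
                    TwoSubstrateParams, VoltageStepProtocol, simulate_condition_set)

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol():
    return VoltageStepProtocol()


@pytest.fixture(scope="session")
def cm_params():
    return ChargeMovementParams()


@pytest.fixture(scope="session")
def cell():
    return CellParams()


@pytest.fixture(scope="session")
def quiet_cell():
    """No capacitance, no leak: the isolated-PSS construction."""
    return CellParams(Cm=0.0, tau_c=1.0, g_leak=0.0)


@pytest.fixture(scope="session")
def transport():
    """Grid generator defaults, dual-effect extension enabled."""
    return TwoSubstrateParams(K_inh=0.3)


@pytest.fixture(scope="session")
def flat_transport():
    """Pinned competitive form with factor(V) = 1 (analytic examples)."""
    return TwoSubstrateParams(voltage_scale=lambda V: np.ones_like(np.asarray(V, float)))


@pytest.fixture(scope="session")
def noise_free_recordings(protocol, cm_params, cell, transport):
    """Blocker + ND98 + one betaine condition, no noise (session-cached)."""
    conds = [SolutionCondition("blocker", blocker=True),
             SolutionCondition("ND98"),
             SolutionCondition("betaine_10mM", betaine_mM=10.0)]
    return simulate_condition_set(protocol, cm_params, cell, transport, conds,
                                  NoiseSpec())
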
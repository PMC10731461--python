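import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from by2sim import reference_params_improved, reference_params_initial
from by2sim.mco import DesignSpace, anchor_points, make_evaluator
from by2sim.process_sim import SolverOptions

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

#: loose-but-adequate solver settings used throughout the suite to keep the
#: simulation-heavy tests fast; accuracy-sensitive tests tighten locally.
FAST = SolverOptions(rtol=1e-6, atol=1e-8)


@pytest.fixture(scope="session")
def ref_initial():
    return reference_params_initial()


@pytest.fixture(scope="session")
def ref_improved():
    return reference_params_improved()


@pytest.fixture(scope="session")
def initial_anchors(ref_initial):
    """Front endpoints of the reference initial model over the default box."""
    space = DesignSpace()
    ev = make_evaluator(ref_initial, space, FAST)
    return anchor_points(ev, space)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
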
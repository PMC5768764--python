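import numpy as np
import pytest

from mmtrack.hypotheses import HypothesisParams
from mmtrack.simdata import SimParams, render_stack, simulate_lineage

LN2 = float(np.log(2.0))


def default_tracking_params() -> HypothesisParams:
    """Hypothesis/cost parameters matched to the default synthetic geometry."""
    return HypothesisParams(typical_length_px=45.0,
                            expected_growth_dlog=LN2 * 0.75 * 180.0 / 3600.0)


@pytest.fixture(scope="session")
def sim_params():
    return SimParams(n_frames=90, seed=12)


@pytest.fixture(scope="session")
def lineage(sim_params):
    return simulate_lineage(sim_params, seed=12)


@pytest.fixture(scope="session")
def stack(lineage):
    return render_stack(lineage, seed=13)


@pytest.fixture(scope="session")
def hyp_params():
    return default_tracking_params()
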
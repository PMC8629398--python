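import numpy as np
import pytest

from avrecal.observer_core import ObserverParams
from avrecal.recalibration_dynamics import RecalibrationDesign


@pytest.fixture(scope="session")
def default_params() -> ObserverParams:
    return ObserverParams()


@pytest.fixture(scope="session")
def flat_prior_params() -> ObserverParams:
    """Truly flat supra-modal prior for limit checks."""
    return ObserverParams(prior_sd=1e6)


def make_recal_design(
    params: ObserverParams | None = None,
    direction: str = "V_right",
    reliability_level: int = 1,
    n_repeats: int = 40,
) -> RecalibrationDesign:
    """Recalibration design of an observer whose perceived-aligned visual
    locations follow exactly from its remapping bias."""
    params = params or ObserverParams()
    a_locs = np.array([-7.5, -2.5, 2.5, 7.5])
    v = params.bias_slope * a_locs + params.bias_intercept
    if direction == "V_right":
        pairs = tuple((a_locs[l], float(v[l + 1])) for l in range(3))
    else:
        pairs = tuple((a_locs[l], float(v[l - 1])) for l in range(1, 4))
    return RecalibrationDesign(
        pairs=pairs,
        reliability_level=reliability_level,
        direction=direction,
        n_repeats=n_repeats,
    )


@pytest.fixture(scope="session")
def recal_design(default_params) -> RecalibrationDesign:
    return make_recal_design(default_params)
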
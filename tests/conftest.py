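import numpy as np
import pytest

from thquorum import DEFAULT_PARAMETERS, IN_VITRO_DENSITY, run_ensemble

NAIVE = np.array([0.1, 0.1, 0.0, 0.0])


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMETERS


@pytest.fixture(scope="session")
def invitro_ensembles(params):
    """Week-long in-vitro ensembles with secretion on and off (shared)."""
    on = run_ensemble(
        100, NAIVE, params, IN_VITRO_DENSITY, secretion_scale=1.0,
        t_span=(0.0, 168.0), master_seed=2024,
    )
    off = run_ensemble(
        100, NAIVE, params, IN_VITRO_DENSITY, secretion_scale=0.0,
        t_span=(0.0, 168.0), master_seed=2024,
    )
    return {"on": on, "off": off}
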
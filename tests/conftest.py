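import numpy as np
import pytest

from bilayerlab import saxs


@pytest.fixture
def step_profile():
    return saxs.StepProfileParams(
        z_m=0.35, z_c=1.4, z_h=1.9, rho_m=-90.0, rho_c=-60.0, rho_h=180.0
    )


@pytest.fixture
def lamellar_params(step_profile):
    return saxs.LamellarModelParams(
        kappa=1.0,
        area=1.0,
        profile=step_profile,
        mct=saxs.MCTParams(N=3, d=21.0, eta=0.05),
        u=0.5,
    )


@pytest.fixture
def q_grid():
    return np.linspace(0.1, 3.0, 300)
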
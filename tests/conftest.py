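import numpy as np
import pytest

from dynreach import PlantConfig, ReachingModel


@pytest.fixture(scope="session")
def results():
    """Fitted lateral-axis controller at the published defaults."""
    return ReachingModel(PlantConfig()).fit()


@pytest.fixture(scope="session")
def factory(results):
    fac = results.conditions()
    fac.onset_step  # resolve the forward-axis calibration once
    return fac


@pytest.fixture(scope="session")
def specs(factory):
    return {name: factory.make(name) for name in (
        "baseline_v", "baseline_nov", "P_nov", "V_shift", "PV_align",
        "PV_conflict",
    )}


@pytest.fixture(scope="session")
def oracle_config():
    """Delay-free, fully observable, multiplicative-noise-free configuration."""
    return PlantConfig(
        delta_p=0, delta_v=0, N=40, p_star=0.2,
        c_parallel=0.0, c_orthogonal=0.0, Sigma_internal=0.0,
        cost_hold_start=None,
    )
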
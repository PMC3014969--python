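import numpy as np
import pytest

from glycowave.models import KineticParams
from glycowave import pde
from glycowave.presets import preset, preset_names


@pytest.fixture(scope="session")
def selkov():
    """Hill-mechanism reference kinetics (Table-panel A-C conditions)."""
    return KineticParams(nu=0.5, sigma=1770.0, q=1.0, n=8, L=1.0, eps=0.0)


@pytest.fixture(scope="session")
def mwc50():
    return KineticParams(nu=0.5, sigma=50.0, q=1.0, n=8, L=1.0e3, eps=1.0)


@pytest.fixture(scope="session")
def mwc60():
    return KineticParams(nu=0.5, sigma=60.0, q=1.0, n=8, L=1.0e3, eps=1.0)


@pytest.fixture(scope="session")
def lowflux_selkov():
    return KineticParams(nu=0.5, sigma=1.0, q=1.0, n=8, L=1.0, eps=0.0,
                         flux_mode="low_flux")


@pytest.fixture(scope="session")
def lowflux_mwc():
    return KineticParams(nu=0.5, sigma=1.0, q=1.0, n=8, L=1.0, eps=1.0,
                         flux_mode="low_flux")


@pytest.fixture(scope="session")
def preset_sims():
    """Scaled (N=88) integrations of all six reference panels, shared across
    the acceptance and diagnostics tests.  Stiff panels run at their largest
    stable time step."""
    out = {}
    for name in preset_names():
        params, cfg = preset(name, N=88, seed=1, stable_dt=True)
        result = pde.integrate(params, cfg)
        out[name] = (result, pde.diagnostics(result))
    return out
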
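import numpy as np
import pytest

import strandflow as sf


@pytest.fixture(scope="session")
def defaults():
    return sf.paper_defaults()


@pytest.fixture(scope="session")
def paper_params(defaults):
    return defaults["params"]


@pytest.fixture(scope="session")
def geometry(defaults):
    return defaults["geometry"]


@pytest.fixture(scope="session")
def fill(defaults):
    return defaults["fill"]


@pytest.fixture(scope="session")
def slip_settings(defaults):
    return defaults["settings"]


@pytest.fixture(scope="session")
def no_slip_settings(defaults):
    return defaults["settings_no_slip"]


@pytest.fixture(scope="session")
def slip_result(defaults):
    d = defaults
    return sf.simulate_extrusion(d["geometry"], d["fill"], d["settings"], d["params"])


@pytest.fixture(scope="session")
def no_slip_result(defaults):
    d = defaults
    return sf.simulate_extrusion(d["geometry"], d["fill"], d["settings_no_slip"],
                                 d["params"])


@pytest.fixture(scope="session")
def plug_geometry():
    """Degenerate straight-tube geometry: outlet radius equals barrel radius."""
    return sf.CartridgeGeometry(barrel_radius=4.8e-3, barrel_length=55e-3,
                                cone_length=1e-9, outlet_radius=4.8e-3)


@pytest.fixture(scope="session")
def plug_result(plug_geometry, defaults):
    d = defaults
    return sf.simulate_extrusion(plug_geometry, d["fill"], d["settings"], d["params"])


@pytest.fixture
def logistic_profile():
    """Densely sampled logistic strand profile with known midpoint and width."""
    s0, w = 0.10, 0.012
    s = np.linspace(0.0, 0.2, 201)
    return sf.StrandProfile(s, 1.0 / (1.0 + np.exp(-(s - s0) / w))), s0, w
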
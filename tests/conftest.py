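import numpy as np
import pytest

import polyion as p


@pytest.fixture(scope="session")
def geometry():
    return p.ScatteringGeometry(wavelength_nm=633.0, angle_deg=173.0,
                                refractive_index=1.33)


@pytest.fixture(scope="session")
def solvent():
    return p.solvent_properties(298.15, 0.0)


@pytest.fixture(scope="session")
def lag_grid():
    return np.geomspace(1e-7, 1e-1, 240)


@pytest.fixture(scope="session")
def isotherm():
    """Default ground-truth charging profile of the simulated polymer."""
    return p.ProtonationIsotherm()


@pytest.fixture(scope="session")
def titration_run(isotherm):
    """Simulated constant-concentration titration with controls, analyzed."""
    design = p.TitrationDesign.logarithmic(n_per_side=240)
    samples, controls = p.simulate_titration(isotherm, design)
    curve = p.analyze_titration(samples, controls)
    return design, samples, controls, curve
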
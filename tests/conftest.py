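import numpy as np
import pytest

from foamdry.kinetics import DryingCurve
from foamdry.synthetic import CurveGenSpec, generate_drying_curve

#: Effective diffusivities (m^2/s) by air temperature (deg C) used as
#: study-condition ground truth throughout the suite.
DEFF_BY_TEMP = {50.0: 5.218e-9, 60.0: 7.150e-9, 70.0: 8.689e-9}

X0 = 3.5657  # initial dry-basis moisture, kg/kg
XE = 0.01  # equilibrium dry-basis moisture, kg/kg
THICKNESS = 0.005  # m


@pytest.fixture(scope="session")
def deff_by_temp():
    return dict(DEFF_BY_TEMP)


@pytest.fixture(scope="session")
def noise_free_curves():
    """Full-series (50-term) noise-free drying curves at the three study
    temperatures, one sample every 4 minutes."""
    curves = {}
    for temp, deff in DEFF_BY_TEMP.items():
        duration = {50.0: 6900.0, 60.0: 5700.0, 70.0: 5100.0}[temp]
        spec = CurveGenSpec(
            deff=deff,
            air_temperature=temp,
            times=np.arange(0.0, duration + 1, 240.0),
            n_terms=50,
        )
        curves[temp] = generate_drying_curve(spec)
    return curves


@pytest.fixture
def linear_curve():
    """Straight-line moisture decay 3.5657 -> 0.01 over 115 min."""
    times = np.linspace(0.0, 115 * 60.0, 24)
    moisture = np.linspace(X0, XE, 24)
    return DryingCurve(times=times, moisture=moisture, air_temperature=50.0)
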
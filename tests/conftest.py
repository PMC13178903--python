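import numpy as np
import pytest

from phantomflow.fields import BLOOD_MIMICKING_FLUID, ScanGrid
from phantomflow.synthetic import AnalyticFieldSpec, make_pulse_waveform, sample_analytic_field


@pytest.fixture(scope="session")
def bmf():
    return BLOOD_MIMICKING_FLUID


@pytest.fixture
def waveform():
    """Default pump waveform: 2.5 L/min plateau, 0.2 s pulse, 1.7 s period."""
    return make_pulse_waveform()


@pytest.fixture
def small_grid():
    return ScanGrid(
        x=np.linspace(-0.02, 0.02, 21),
        y=np.linspace(-0.02, 0.02, 21),
        t=np.linspace(0.0, 0.1, 5),
    )


@pytest.fixture
def stagnation_spec(bmf):
    return AnalyticFieldSpec(kind="stagnation", parameters={"k": 20.0}, fluid=bmf)


@pytest.fixture
def rotation_spec(bmf):
    return AnalyticFieldSpec(kind="solid_body_rotation", parameters={"omega": 30.0}, fluid=bmf)


@pytest.fixture
def stagnation_field(stagnation_spec, small_grid):
    return sample_analytic_field(stagnation_spec, small_grid)


@pytest.fixture
def rotation_field(rotation_spec, small_grid):
    return sample_analytic_field(rotation_spec, small_grid)
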
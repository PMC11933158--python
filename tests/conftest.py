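import numpy as np
import pytest

from pisaflow.geometry import load_catalog, make_orifice
from pisaflow.pisa_estimator import BeamSpec
from pisaflow.synthetic_flow import (FieldSeries, JetSpec, Waveform,
                                     default_phases, jet_exit_series,
                                     point_sink_field)

#: reference steady flow rate of the convergence-zone analyses (ml/s)
Q_REF = 244.9


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def circle_L():
    return make_orifice("circle", 12.2, label="circle-L")


@pytest.fixture(scope="session")
def sink_grid():
    """Fine 2-D grid upstream of the orifice (0.25 mm spacing)."""
    x = np.arange(-3.6, -0.0999, 0.025)
    y = np.arange(-0.3, 0.3001, 0.025)
    return x, y


@pytest.fixture(scope="session")
def sink_field(sink_grid):
    return point_sink_field(Q_REF, *sink_grid)


@pytest.fixture(scope="session")
def sink_series(sink_field):
    return FieldSeries(np.array([0.0]), [sink_field])


@pytest.fixture(scope="session")
def aligned_beam():
    return BeamSpec(direction=(-1.0, 0.0))


def make_circle_jet_series(target_rvol: float, spacing: float = 0.0125):
    """Pulsatile circle-L jet series scaled to a programmed RVol (ml),
    on a 2-D mid-plane grid suitable for axisymmetric evaluation."""
    orf = make_orifice("circle", 12.2, label="circle-L")
    wf = Waveform()
    wf = wf.scaled(target_rvol / (orf.area_cm2 * wf.integral()))
    jet = JetSpec(orf, wf)
    x = np.array([0.0, 0.1])
    y = np.arange(-0.85, 0.8501, spacing)
    return jet, jet_exit_series(jet, x, y, phases=default_phases())


@pytest.fixture(scope="session")
def circle_jet_30ml():
    return make_circle_jet_series(30.0)
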
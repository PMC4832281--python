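import numpy as np
import pytest

from camdecode.binding import BaseParameters, BindingModel, steady_state
from camdecode.genes import GeneParams
from camdecode.signatures import PiecewiseSpec, make_piecewise


@pytest.fixture(scope="session")
def model():
    """Reference binding network (printed constants, 10 uM totals)."""
    return BindingModel()


@pytest.fixture(scope="session")
def gene_params():
    return GeneParams()


@pytest.fixture(scope="session")
def control_state(model):
    """Equilibrium at the resting Ca2+ level 0.10 uM."""
    return steady_state(model, model.control_ca)


@pytest.fixture(scope="session")
def reference_spec():
    """The square-wave reconstruction of the measured oscillatory signature."""
    return PiecewiseSpec(average=0.16, ca_max=0.52, ca_min=0.10,
                         period=40.0, duration=400.0)


@pytest.fixture(scope="session")
def short_spec():
    """A three-cycle square wave, cheap enough for dynamical unit tests."""
    return PiecewiseSpec(average=0.16, ca_max=0.52, ca_min=0.10,
                         period=40.0, duration=120.0)


@pytest.fixture(scope="session")
def short_trace(short_spec):
    return make_piecewise(short_spec)
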
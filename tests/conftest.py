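import numpy as np
import pytest

from hibrain import Model, ParameterSet
from hibrain.simulate import InputTraces, Protocol, simulate


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def model(params):
    return Model(params)


@pytest.fixture(scope="session")
def insult_run(model):
    """One full insult simulation (10 min baseline, 20 min desaturation +
    occlusion, 30 min recovery) with clean step inputs, shared across
    tests."""
    prot = Protocol()
    t = np.arange(0.0, prot.duration + 60.0, 60.0)
    sao2 = np.full_like(t, model.params.SaO2_n)
    during = (t >= prot.t_occlude) & (t <= prot.t_release)
    sao2[during] = 0.30
    traces = InputTraces(time=t, SaO2=sao2,
                         Pa=np.full_like(t, model.params.P_a_n))
    return simulate(model, traces, prot, output_dt=30.0)
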
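import warnings

import numpy as np
import pytest
from hypothesis import settings

import hemotevp as h

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def mcmillan():
    return h.load_preset("mcmillan1987_subject")


@pytest.fixture(scope="session")
def armstrong():
    return h.load_preset("armstrong2018_donor1")


@pytest.fixture(scope="session")
def ucm_params():
    """Degenerate parameter set reducing the model to upper-convected
    Maxwell: no yield stress, no PTT nonlinearity, frozen structure."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return h.ModelParameters(G=0.382, eta0=0.012, tau_y=0.0, eps_ptt=0.0,
                                 k1=0.1, k2=0.0, k3=0.0,
                                 n1=1.0, n2=2.0, n3=1.0, m1=1.0)


@pytest.fixture(scope="session")
def intermittent_rheogram(mcmillan):
    """The rectangular shear-step record: 7 1/s pulses of 2.5 s separated
    by 1.5 s rests, two pulses, trailing rest (8 s record)."""
    spec = h.ProtocolSpec.intermittent(7.0, 2.5, 1.5, n_pulses=2)
    return h.integrate(spec, mcmillan)


@pytest.fixture(scope="session")
def cessation_rheograms(mcmillan):
    """Startup-then-cessation records at 7.1 and 14.1 1/s, t_ces = 3 s."""
    out = {}
    for rate in (7.1, 14.1):
        spec = h.ProtocolSpec.cessation(rate, 3.0, t_end=40.0)
        out[rate] = h.integrate(spec, mcmillan)
    return out


def rel_err(value, reference):
    return abs(value - reference) / abs(reference)


@pytest.fixture(scope="session")
def random_symmetric_tensors():
    rng = np.random.default_rng(7)
    out = []
    for _ in range(20):
        c = rng.normal(scale=2.0, size=6)
        out.append(h.SymmetricTensor(*c))
    return out
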
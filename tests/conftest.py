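import numpy as np
import pytest

import mainferm as mf

GROWTH_TR = mf.GrowthParams(0.103, 0.0381)
YIELD_TR = mf.YieldLinearSmoothed(a=7.55, b=0.808, N_dagger=0.176)
SECOND_TR = mf.SecondStepParams(k=2.17, beta=2.41, mu_S_max=0.197,
                                      K_S=21.1, K_E=72.7)
GROWTH_SOFA = mf.GrowthParams(0.270, 0.00952)
YIELD_SOFA = mf.YieldQuadExp(a=15.1, b=15.2, N_dagger=0.465)


@pytest.fixture(scope="session")
def transporter():
    return mf.load_preset("transporter-2022")


@pytest.fixture(scope="session")
def sofa():
    return mf.load_preset("sofa-2022")


@pytest.fixture(scope="session")
def experimental():
    return mf.load_preset("experimental-2022")


@pytest.fixture(scope="session")
def all_presets(transporter, sofa, experimental):
    return {"transporter-2022": transporter, "sofa-2022": sofa,
            "experimental-2022": experimental}


@pytest.fixture(scope="session")
def chronicle_tr_567(transporter):
    """Noiseless standard-conditions chronicle, N0 = 0.567, shared read-only."""
    ps = transporter
    return mf.simulate(mf.with_n0(0.567), ps.growth, ps.yield_fn,
                       ps.second_step)


@pytest.fixture(scope="session")
def chronicles_tr(transporter):
    chs, _ = mf.gen_chronicles(transporter)
    return chs


def rel_err(est, true):
    return abs(est - true) / abs(true)


def contois_curve(gp, r):
    return gp.mu_N_max * np.asarray(r) / (gp.K_N + np.asarray(r))
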
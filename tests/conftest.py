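import numpy as np
import pytest
from hypothesis import settings

import il10pkpd as m
from il10pkpd import reference as R
from il10pkpd.dosing import (
    MW_MONKEY_CONSTRUCT,
    MW_MOUSE_CONSTRUCT,
    Route,
    SimGrid,
    build_regimen,
)
from il10pkpd.profiles import Profile

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mouse_pk():
    return R.mouse_pk_reference()  # efficacy-study Vc 0.045 L/kg


@pytest.fixture(scope="session")
def monkey_pk():
    return R.monkey_pk_reference()


@pytest.fixture(scope="session")
def mouse_il18():
    return R.mouse_il18_reference()


@pytest.fixture(scope="session")
def monkey_il18():
    return R.monkey_il18_reference()


@pytest.fixture(scope="session")
def platelet_params():
    return R.platelet_reference()


@pytest.fixture(scope="session")
def hct_params():
    return R.hematocrit_reference()


def single_ip_regimen(dose, mw=MW_MOUSE_CONSTRUCT):
    return build_regimen(dose, 14, 1, Route.IP_FIRST_ORDER, mw=mw)


def q2w_iv_regimen(dose, n_doses=3, factors=(), mw=MW_MONKEY_CONSTRUCT):
    return build_regimen(dose, 14, n_doses, Route.IV_BOLUS,
                         reduction_factors=factors, mw=mw)


def zero_profile(t_end, step=0.25):
    t = SimGrid(0.0, t_end, step).times()
    return Profile(times=t, values=np.zeros(t.size), unit="nM", name="Cp")


@pytest.fixture(scope="session")
def monkey_repeat_pk_forcing(monkey_pk):
    """Truth PK forcing profiles for the repeat-dose study arms
    (with ADA reduction factors), on a grid covering 6+ weeks."""
    grid = SimGrid(0.0, 1056.0, 0.25)
    out = {"vehicle": zero_profile(1056.0)}
    for label, dose, rf in (
        ("rd-0.06", 0.06, (1.0, 3.0, 4.9)),
        ("rd-0.18", 0.18, (1.0, 2530.0, 380.0)),
    ):
        out[label] = m.simulate_monkey_pk(
            monkey_pk, q2w_iv_regimen(dose, factors=rf), grid
        )
    return out
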
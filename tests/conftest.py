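import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from fosfopk.datagen import generate_cohort
from fosfopk.model import FixedEffects, IndividualParams, RandomEffects


@pytest.fixture(scope="session")
def fx():
    return FixedEffects()


@pytest.fixture(scope="session")
def re_():
    return RandomEffects()


@pytest.fixture(scope="session")
def cohort_df():
    """One synthetic four-study cohort at the published truth."""
    return generate_cohort(seed=20240901)


@pytest.fixture
def typical_params(fx):
    """Typical subject at the reference eGFR, constant peripheral volume."""
    return IndividualParams(
        cl_body=fx.theta_cl,
        v_c=fx.theta_vc,
        v_p0=fx.theta_vp,
        vp_slope_per_h=0.0,
        q=fx.theta_q,
        theta_dial=fx.theta_dial,
        theta_qd=fx.theta_qd,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
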
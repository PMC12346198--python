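import numpy as np
import pytest

from prodrugpk.compounds import ROUTE_IV, Compound, DoseEvent, default_registry
from prodrugpk.model import CombinedModelParams, DispositionParams


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def niclosamide(registry):
    return registry["niclosamide"]


@pytest.fixture
def iv_dose(niclosamide):
    return DoseEvent(
        subject_id="m1", time=0.0, route=ROUTE_IV, dose_mg_per_kg=2.0, compound=niclosamide
    )


@pytest.fixture
def two_cpt_params():
    return DispositionParams(CL=0.08, Vc=0.15, Q=0.05, Vp=0.3, Ka=1.0, F=0.3)


@pytest.fixture
def combined_params(two_cpt_params):
    prodrug = DispositionParams(CL=0.02, Vc=0.008, Q=0.01, Vp=0.05, Ka=0.6, F=0.27)
    return CombinedModelParams(prodrug=prodrug, parent=two_cpt_params, Fm=0.23)


@pytest.fixture
def dense_times():
    return np.linspace(0.0, 24.0, 481)
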
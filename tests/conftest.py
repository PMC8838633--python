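import numpy as np
import pytest

from chijva.cohort import ConditionLevel, ParticipantModel
from chijva.pipeline import make_fixtures


@pytest.fixture(scope="session")
def fixture_bundle():
    """Small noise-free scene/stack/signal bundle with exact ground truth."""
    return make_fixtures(seed=7)


@pytest.fixture()
def participant():
    return ParticipantModel(
        id="T01", sex="M", hb_scale=1.1, scm_thickness=1.0, ijv_depth=1.4,
        csa_baseline=0.5, jva_gain=0.2, heart_rate=66.0, resp_rate=14.0,
        hdt_delta=0.18, lbnp_max_reduction=0.7,
    )


@pytest.fixture()
def hdt0():
    return ConditionLevel("HDT", 0.0)
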
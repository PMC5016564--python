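import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from bacips.design import SamplingOccasion, StudyDesign, classify_sessions
from bacips.simulate import make_desk_design, make_seasonal_study_design

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def seasonal_design():
    return make_seasonal_study_design()


@pytest.fixture(scope="session")
def desk_design():
    return make_desk_design()


@pytest.fixture()
def three_occasion_design():
    """Three quarterly occasions with unit exponents (base period = spacing)."""
    occ = [
        SamplingOccasion(i, dt.date(2008, 1, 1) + dt.timedelta(days=91 * i), "winter")
        for i in range(3)
    ]
    design = StudyDesign(
        occasions=occ, installation_date=dt.date(2008, 4, 1), base_period_days=91
    )
    classify_sessions(design)
    return design
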
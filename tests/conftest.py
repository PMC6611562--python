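import datetime

import pytest

from vocburden.codesets import StudyConfig, default_config
from vocburden.cohort import Claim, EnrollmentSpan


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    return default_config()


def make_claim(
    claim_id="C1",
    patient_id="P1",
    start="2011-01-01",
    end=None,
    place="office",
    dx=("28242",),
):
    start = datetime.date.fromisoformat(start) if isinstance(start, str) else start
    if end is None:
        end = start
    end = datetime.date.fromisoformat(end) if isinstance(end, str) else end
    return Claim(
        claim_id=claim_id,
        patient_id=patient_id,
        service_start=start,
        service_end=end,
        place_of_service=place,
        dx=tuple(dx),
    )


def make_span(
    patient_id="P1",
    start="2009-01-01",
    end="2013-12-31",
    medical=True,
    pharmacy=True,
    dual=False,
):
    return EnrollmentSpan(
        patient_id=patient_id,
        start=datetime.date.fromisoformat(start),
        end=datetime.date.fromisoformat(end),
        medical=medical,
        pharmacy=pharmacy,
        dual_eligible=dual,
    )


def day(offset: int, origin: datetime.date = datetime.date(2011, 1, 1)) -> datetime.date:
    return origin + datetime.timedelta(days=offset)
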
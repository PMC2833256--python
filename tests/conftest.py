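import pytest

from respcrit import (
    CriteriaThresholds,
    LesionMeasurement,
    OrganSite,
    PatientTimeline,
    Scan,
)


@pytest.fixture(scope="session")
def thresholds():
    return CriteriaThresholds()


def _lesion(lid, site=OrganSite.LUNG, d=30.0, hu=60.0, **kw):
    return LesionMeasurement(lid, site, d, hu, **kw)


@pytest.fixture()
def lesion_factory():
    return _lesion


@pytest.fixture()
def simple_timeline():
    """One patient: a 48 mm / 107 HU lung lesion shrinking to 39 mm / 65 HU."""
    baseline = Scan(0.0, (_lesion("L0", d=48.0, hu=107.0),))
    evaluation = Scan(1.9, (_lesion("L0", d=39.0, hu=65.0),))
    return PatientTimeline(
        patient_id="P1",
        scans=[baseline, evaluation],
        last_followup_months=12.0,
    )
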
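import pytest

from premicc.events import TimeToEventRecord
from premicc.synthetic_data import CohortConfig, generate_cohort


def tte(pid, time, event, risk_class=None):
    return TimeToEventRecord(
        patient_id=pid, time_months=time, event=event, risk_class=risk_class
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scenario synthetic cohort (88 + 113 patients)."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def toy_curve_records():
    """n=5: events at 2 and 4; censored at 3, 5, 5."""
    return [
        tte("a", 2.0, True),
        tte("b", 3.0, False),
        tte("c", 4.0, True),
        tte("d", 5.0, False),
        tte("e", 5.0, False),
    ]
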
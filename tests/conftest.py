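import datetime as dt

import pytest

from aquacpi.types import (
    CensorFlag,
    Measurement,
    MonitoringSeries,
    ObjectiveSpec,
    ParameterDef,
)

CHEM = ParameterDef(code="X", name="generic", unit="mg/L", group="chemical")
MICRO = ParameterDef(code="TC", name="Total coliforms", unit="MPN/100mL", group="biological")


def make_series(values, parameter=CHEM, facility="F1", censored=None):
    """Series with daily dates; `censored` lists indices reported as non-detects."""
    censored = set(censored or ())
    measurements = []
    for i, v in enumerate(values):
        date = dt.date(2020, 1, 1) + dt.timedelta(days=i)
        if i in censored:
            measurements.append(
                Measurement(
                    date=date,
                    value=v,
                    censored=CensorFlag.below_detection,
                    detection_limit=v,
                )
            )
        else:
            measurements.append(Measurement(date=date, value=v))
    return MonitoringSeries(
        facility_id=facility, parameter=parameter, measurements=measurements
    )


@pytest.fixture
def upper10():
    return ObjectiveSpec(bound_type="upper", high=10)


@pytest.fixture
def ph_range():
    return ObjectiveSpec(bound_type="range", low=6, high=8.4)


@pytest.fixture
def absent():
    return ObjectiveSpec(bound_type="absent")
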
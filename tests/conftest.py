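from datetime import datetime, timedelta

import pytest

from labwatch.hl7_io import LabResult, Source
from labwatch.rules import Parameter, build_default_rulesets

T0 = datetime(2021, 3, 1, 8, 0, 0)


def make_result(
    parameter=Parameter.K,
    value=4.0,
    at=T0,
    patient_id="1002",
    case_id=None,
    order_id="O1",
    source=Source.LAB,
):
    return LabResult(
        measured_at=at,
        patient_id=patient_id,
        case_id=case_id or f"C{patient_id}",
        order_id=order_id,
        parameter=parameter,
        value=value,
        source=source,
    )


@pytest.fixture
def rulesets():
    return build_default_rulesets()


@pytest.fixture
def rules_by_id(rulesets):
    return {r.algorithm_id: r for r in rulesets}


@pytest.fixture
def t0():
    return T0


def hours(h):
    return timedelta(hours=h)
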
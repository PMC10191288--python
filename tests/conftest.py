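from datetime import date

import pytest

from divpheno import load_trigger_lexicon
from divpheno.phecodes import load_phecode_definitions, load_phecode_map
from divpheno.phenotyping import CodeEvent, PatientRecord, ProcedureEvent
from divpheno.clinical_text import ReportDocument


@pytest.fixture(scope="session")
def triggers():
    return load_trigger_lexicon()


@pytest.fixture(scope="session")
def phecode_map():
    return load_phecode_map()


@pytest.fixture(scope="session")
def phecode_defs():
    return load_phecode_definitions()


def make_record(
    pid="P1",
    report_texts=(),
    report_type="colonoscopy",
    codes=(),
    proc_dates=(),
    **kwargs,
):
    """Small helper to build a PatientRecord from shorthand."""
    d0 = date(2015, 6, 1)
    reports = [ReportDocument(pid, report_type, d0, t) for t in report_texts]
    code_events = [
        CodeEvent(pid, system, code, when) for system, code, when in codes
    ]
    procs = [ProcedureEvent(pid, "colonoscopy", d) for d in proc_dates]
    return PatientRecord(
        patient_id=pid, reports=reports, codes=code_events, procedures=procs, **kwargs
    )


@pytest.fixture
def record_factory():
    return make_record
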
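"""Case/control phenotyping algorithms for diverticulosis and diverticulitis.

Three algorithms operate on a :class:`PatientRecord`:

* ``classify_nlp`` — scans the free text of colonoscopy / abdominal-imaging
  reports for positively asserted ``diverticul*`` mentions, supplemented by
  diagnostic codes;
* ``classify_structured`` — driven by ICD codes assigned within a
  configurable window (default 7 days, inclusive) after a colonoscopy or
  abdominal imaging procedure, supplemented by report text when available;
* ``classify_icd_comparator`` — the traditional phecode-based comparator
  that consults coded diagnoses only.

All algorithms enforce the clinical containment: a diverticulitis case is
always also a diverticulosis case. Validation (PPV against chart-review
gold labels) and head-to-head comparison statistics live here too.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .clinical_text import (
    ReportDocument,
    annotate,
    load_trigger_lexicon,
    summarize_document,
)

QUALIFYING_REPORT_TYPES = frozenset({"colonoscopy", "abdominal_imaging"})

#: ICD prefixes that mark the diverticular-disease code family
DD_CODE_PREFIXES = {"ICD9CM": ("562",), "ICD10CM": ("K57",)}


class Status(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"
    EXCLUDED = "excluded"
    UNCLASSIFIED = "unclassified"


class Algorithm(str, enum.Enum):
    NLP = "nlp"
    STRUCTURED = "structured"
    ICD_COMPARATOR = "icd_comparator"


@dataclass(frozen=True)
class CodeEvent:
    patient_id: str
    system: str  # ICD9CM | ICD10CM | CPT4
    code: str  # dot-normalized, e.g. "562.11", "K57.32"
    date: date

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("code must be non-empty")


@dataclass(frozen=True)
class ProcedureEvent:
    patient_id: str
    kind: str  # colonoscopy | abdominal_imaging
    date: date


@dataclass
class PatientRecord:
    patient_id: str
    sex: str = "F"
    age_at_colonoscopy: float = 0.0
    site: str = ""
    ancestry: str = "other"
    reports: list[ReportDocument] = field(default_factory=list)
    codes: list[CodeEvent] = field(default_factory=list)
    procedures: list[ProcedureEvent] = field(default_factory=list)


@dataclass
class PhenotypeAssignment:
    patient_id: str
    algorithm: Algorithm
    diverticulosis: Status
    diverticulitis: Status
    evidence: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.diverticulitis is Status.CASE and self.diverticulosis is not Status.CASE:
            raise ValueError("diverticulitis case implies diverticulosis case")
        if (self.diverticulosis is Status.EXCLUDED) != (self.diverticulitis is Status.EXCLUDED):
            raise ValueError("exclusion applies to both conditions or neither")


@dataclass(frozen=True)
class ValidationReport:
    n_cases_reviewed: int
    n_controls_reviewed: int
    ppv_case: float | None
    ppv_control: float | None


@dataclass(frozen=True)
class ComparisonReport:
    n_A: int
    n_B: int
    n_overlap: int | None
    fold_increase: float | None
    overlap_fraction_of_A: float | None


def _load_tsv(name: str) -> list[dict[str, str]]:
    with resources.files("divpheno.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def default_exclusion_prefixes() -> list[tuple[str, str]]:
    """(system, code-prefix) pairs whose presence excludes a patient."""
    return [(row["system"], row["prefix"]) for row in _load_tsv("exclusion_codes.tsv")]


def default_diverticulitis_codes() -> frozenset[tuple[str, str]]:
    """ICD codes that specifically indicate diverticulitis."""
    return frozenset((row["system"], row["code"]) for row in _load_tsv("diverticulitis_codes.tsv"))


def apply_exclusions(
    record: PatientRecord, exclusions: Sequence[tuple[str, str]] | None = None
) -> bool:
    """True iff any code event matches an exclusion prefix under its system."""
    if exclusions is None:
        exclusions = default_exclusion_prefixes()
    for ev in record.codes:
        for system, prefix in exclusions:
            if ev.system == system and ev.code.startswith(prefix):
                return True
    return False


def _has_dd_code(record: PatientRecord) -> bool:
    return any(
        ev.code.startswith(DD_CODE_PREFIXES.get(ev.system, ()))
        for ev in record.codes
    )


def _itis_code_events(
    record: PatientRecord, itis_codes: frozenset[tuple[str, str]]
) -> list[CodeEvent]:
    return [ev for ev in record.codes if (ev.system, ev.code) in itis_codes]


def _nlp_document_flags(record: PatientRecord, triggers=None):
    """Per-document positivity flags over qualifying reports."""
    if triggers is None:
        triggers = load_trigger_lexicon()
    flags = []
    for report in record.reports:
        if report.report_type not in QUALIFYING_REPORT_TYPES:
            continue
        mentions = annotate(report.text, triggers)
        flags.append((report, summarize_document(mentions)))
    return flags


def classify_nlp(
    record: PatientRecord,
    exclusions: Sequence[tuple[str, str]] | None = None,
    triggers=None,
    itis_codes: frozenset[tuple[str, str]] | None = None,
) -> PhenotypeAssignment:
    """NLP-driven phenotyping from colonoscopy/imaging report text.

    Any report with a positively asserted diverticulitis mention makes the
    patient a case for both conditions; a positively asserted diverticulosis
    mention alone makes a diverticulosis case (diverticulitis control). A
    diverticulitis-specific diagnosis code can additionally promote an
    NLP-positive diverticulosis patient to diverticulitis case (codes
    supplement the text; they never demote). Controls require at least one
    qualifying report, no positive mention, and no diverticular ICD code
    ever; everyone else is unclassified.
    """
    if itis_codes is None:
        itis_codes = default_diverticulitis_codes()
    if apply_exclusions(record, exclusions):
        return PhenotypeAssignment(
            record.patient_id, Algorithm.NLP, Status.EXCLUDED, Status.EXCLUDED,
            evidence=[("exclusion", "exclusion-list code present")],
        )
    flags = _nlp_document_flags(record, triggers)
    evidence: list[tuple[str, str]] = []
    pos_itis = False
    pos_osis = False
    for report, doc in flags:
        if doc.positive_diverticulitis:
            pos_itis = True
            evidence.append(("report", f"{report.report_type}@{report.report_date}: diverticulitis"))
        elif doc.positive_diverticulosis:
            pos_osis = True
            evidence.append(("report", f"{report.report_type}@{report.report_date}: diverticulosis"))
    if pos_itis:
        return PhenotypeAssignment(record.patient_id, Algorithm.NLP, Status.CASE, Status.CASE, evidence)
    if pos_osis:
        itis_events = _itis_code_events(record, itis_codes)
        if itis_events:
            evidence.append(("code", f"{itis_events[0].system} {itis_events[0].code}"))
            return PhenotypeAssignment(record.patient_id, Algorithm.NLP, Status.CASE, Status.CASE, evidence)
        return PhenotypeAssignment(record.patient_id, Algorithm.NLP, Status.CASE, Status.CONTROL, evidence)
    if flags and not _has_dd_code(record):
        return PhenotypeAssignment(
            record.patient_id, Algorithm.NLP, Status.CONTROL, Status.CONTROL,
            evidence=[("report", "qualifying reports without positive mention")],
        )
    return PhenotypeAssignment(record.patient_id, Algorithm.NLP, Status.UNCLASSIFIED, Status.UNCLASSIFIED)


def classify_structured(
    record: PatientRecord,
    exclusions: Sequence[tuple[str, str]] | None = None,
    window_days: int = 7,
    triggers=None,
    itis_codes: frozenset[tuple[str, str]] | None = None,
) -> PhenotypeAssignment:
    """Structured-data-driven phenotyping (codes anchored to procedures).

    A diverticular ICD code dated within ``[p, p + window_days]`` (both ends
    inclusive) of a colonoscopy or abdominal-imaging procedure date ``p``
    makes a diverticulosis case; a diverticulitis-specific code in that
    window makes a diverticulitis case. When report text exists, NLP
    positivity is merged in by OR. Controls need at least one procedure,
    zero diverticular codes ever, and no positive text mention.
    """
    if itis_codes is None:
        itis_codes = default_diverticulitis_codes()
    if apply_exclusions(record, exclusions):
        return PhenotypeAssignment(
            record.patient_id, Algorithm.STRUCTURED, Status.EXCLUDED, Status.EXCLUDED,
            evidence=[("exclusion", "exclusion-list code present")],
        )
    window = timedelta(days=window_days)
    proc_dates = [p.date for p in record.procedures]
    evidence: list[tuple[str, str]] = []
    case_osis = False
    case_itis = False
    for ev in record.codes:
        if not ev.code.startswith(DD_CODE_PREFIXES.get(ev.system, ())):
            continue
        if any(p <= ev.date <= p + window for p in proc_dates):
            case_osis = True
            evidence.append(("code", f"{ev.system} {ev.code}@{ev.date}"))
            if (ev.system, ev.code) in itis_codes:
                case_itis = True
    pos_osis_nlp = pos_itis_nlp = False
    flags = _nlp_document_flags(record, triggers)
    for report, doc in flags:
        pos_osis_nlp = pos_osis_nlp or doc.positive_diverticulosis
        pos_itis_nlp = pos_itis_nlp or doc.positive_diverticulitis
    if pos_itis_nlp:
        evidence.append(("report", "positive diverticulitis mention"))
    elif pos_osis_nlp:
        evidence.append(("report", "positive diverticulosis mention"))
    case_osis = case_osis or pos_osis_nlp or pos_itis_nlp
    case_itis = case_itis or pos_itis_nlp
    if case_itis:
        return PhenotypeAssignment(record.patient_id, Algorithm.STRUCTURED, Status.CASE, Status.CASE, evidence)
    if case_osis:
        return PhenotypeAssignment(record.patient_id, Algorithm.STRUCTURED, Status.CASE, Status.CONTROL, evidence)
    if proc_dates and not _has_dd_code(record) and not pos_osis_nlp:
        return PhenotypeAssignment(
            record.patient_id, Algorithm.STRUCTURED, Status.CONTROL, Status.CONTROL,
            evidence=[("procedure", "examined without diverticular codes or mentions")],
        )
    return PhenotypeAssignment(
        record.patient_id, Algorithm.STRUCTURED, Status.UNCLASSIFIED, Status.UNCLASSIFIED
    )


def classify_icd_comparator(
    record: PatientRecord,
    phecode_map: Mapping[tuple[str, str], str],
    exclusions: Sequence[tuple[str, str]] | None = None,
) -> PhenotypeAssignment:
    """Traditional phecode-based comparator; consults coded diagnoses only.

    Case iff any event maps to phecode 562 or a child (562.1 diverticulosis,
    562.2 diverticulitis); diverticulitis case iff any maps to 562.2.
    Would-be controls carrying an exclusion-list code are excluded instead.
    """
    from .phecodes import map_icd_to_phecode  # local import avoids a cycle

    if exclusions is None:
        exclusions = default_exclusion_prefixes()
    dd_case = itis_case = False
    evidence: list[tuple[str, str]] = []
    for ev in record.codes:
        phecodes = map_icd_to_phecode(ev, phecode_map)
        if any(p in ("562", "562.1", "562.2") for p in phecodes):
            dd_case = True
            evidence.append(("code", f"{ev.system} {ev.code}"))
        if "562.2" in phecodes:
            itis_case = True
    if dd_case:
        return PhenotypeAssignment(
            record.patient_id, Algorithm.ICD_COMPARATOR,
            Status.CASE, Status.CASE if itis_case else Status.CONTROL, evidence,
        )
    if apply_exclusions(record, exclusions):
        return PhenotypeAssignment(
            record.patient_id, Algorithm.ICD_COMPARATOR, Status.EXCLUDED, Status.EXCLUDED,
            evidence=[("exclusion", "exclusion-list code present")],
        )
    return PhenotypeAssignment(
        record.patient_id, Algorithm.ICD_COMPARATOR, Status.CONTROL, Status.CONTROL
    )


def classify_cohort(
    records: Iterable[PatientRecord],
    algorithm: Algorithm,
    phecode_map: Mapping[tuple[str, str], str] | None = None,
    exclusions: Sequence[tuple[str, str]] | None = None,
    window_days: int = 7,
    triggers=None,
) -> list[PhenotypeAssignment]:
    """Run one algorithm over a cohort (shared lexicon load)."""
    if triggers is None and algorithm in (Algorithm.NLP, Algorithm.STRUCTURED):
        triggers = load_trigger_lexicon()
    out = []
    for rec in records:
        if algorithm is Algorithm.NLP:
            out.append(classify_nlp(rec, exclusions, triggers))
        elif algorithm is Algorithm.STRUCTURED:
            out.append(classify_structured(rec, exclusions, window_days, triggers))
        elif algorithm is Algorithm.ICD_COMPARATOR:
            if phecode_map is None:
                from .phecodes import load_phecode_map

                phecode_map = load_phecode_map()
            out.append(classify_icd_comparator(rec, phecode_map, exclusions))
        else:  # pragma: no cover
            raise ValueError(f"unknown algorithm {algorithm}")
    return out


def compute_ppv(
    assignments: Iterable[PhenotypeAssignment],
    gold: Mapping[str, bool],
    condition: str = "diverticulosis",
) -> ValidationReport:
    """Positive predictive values against chart-review gold labels.

    ``gold`` maps patient id -> True (condition present) / False (absent)
    for the reviewed patients. PPV of a stratum with zero reviewed patients
    is reported as missing (None), never as 0.
    """
    by_id = {a.patient_id: a for a in assignments}
    missing = [pid for pid in gold if pid not in by_id]
    if missing:
        raise KeyError(f"no assignment for reviewed patients: {missing[:5]}")
    case_total = case_hit = ctrl_total = ctrl_hit = 0
    for pid, truth in gold.items():
        status = getattr(by_id[pid], condition)
        if status is Status.CASE:
            case_total += 1
            case_hit += bool(truth)
        elif status is Status.CONTROL:
            ctrl_total += 1
            ctrl_hit += not truth
    return ValidationReport(
        n_cases_reviewed=case_total,
        n_controls_reviewed=ctrl_total,
        ppv_case=case_hit / case_total if case_total else None,
        ppv_control=ctrl_hit / ctrl_total if ctrl_total else None,
    )


def compare_algorithms(
    cases_a: Iterable[str] | int,
    cases_b: Iterable[str] | int,
    n_overlap: int | None = None,
) -> ComparisonReport:
    """Head-to-head case-count comparison of two phenotyping algorithms.

    Accepts either case-id sets (overlap computed) or published counts
    (``cases_a``, ``cases_b`` integers, ``n_overlap`` optionally given).
    Reports the fold increase n_A / n_B and the overlap as a fraction of
    algorithm A's cases; a statistic whose denominator (or overlap count)
    is unavailable is reported missing (None), never 0.
    """
    if isinstance(cases_a, int):
        n_a, n_b = cases_a, int(cases_b)
    else:
        set_a, set_b = set(cases_a), set(cases_b)
        n_a, n_b = len(set_a), len(set_b)
        n_overlap = len(set_a & set_b)
    if n_overlap is not None and n_overlap > min(n_a, n_b):
        raise ValueError("overlap cannot exceed either case count")
    return ComparisonReport(
        n_A=n_a,
        n_B=n_b,
        n_overlap=n_overlap,
        fold_increase=n_a / n_b if n_b else None,
        overlap_fraction_of_A=(n_overlap / n_a) if (n_overlap is not None and n_a) else None,
    )


def case_ids(assignments: Iterable[PhenotypeAssignment], condition: str) -> set[str]:
    return {a.patient_id for a in assignments if getattr(a, condition) is Status.CASE}


def summarize_cohort(n_cases: int, n_controls: int) -> dict[str, float]:
    """Basic cohort accounting: total subjects and case fraction (percent)."""
    total = n_cases + n_controls
    return {
        "n_cases": n_cases,
        "n_controls": n_controls,
        "n_total": total,
        "case_fraction_pct": 100.0 * n_cases / total if total else float("nan"),
    }
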
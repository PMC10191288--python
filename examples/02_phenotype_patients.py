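"""Phenotype three hand-built patients with all three algorithms.

Shows how the text-driven, structured (7-day code window) and phecode
comparator algorithms can disagree on the same evidence.
"""

from datetime import date

from divpheno import (
    Algorithm,
    CodeEvent,
    PatientRecord,
    ProcedureEvent,
    ReportDocument,
    classify_cohort,
)
from divpheno.clinical_text import ReportDocument

d = date(2018, 5, 1)
patients = [
    # positive report, never coded: the text algorithm finds the case
    PatientRecord(
        "A",
        reports=[ReportDocument("A", "colonoscopy", d, "Sigmoid diverticulosis noted.")],
        procedures=[ProcedureEvent("A", "colonoscopy", d)],
    ),
    # coded 3 days after the procedure, no report available
    PatientRecord(
        "B",
        codes=[CodeEvent("B", "ICD9CM", "562.11", date(2018, 5, 4))],
        procedures=[ProcedureEvent("B", "colonoscopy", d)],
    ),
    # clean colonoscopy, no diverticular codes: a control
    PatientRecord(
        "C",
        reports=[ReportDocument("C", "colonoscopy", d, "No diverticula or masses identified.")],
        procedures=[ProcedureEvent("C", "colonoscopy", d)],
    ),
]

for algo in Algorithm:
    print(f"\n{algo.value}:")
    for a in classify_cohort(patients, algo):
        print(f"  {a.patient_id}: diverticulosis={a.diverticulosis.value:12s} "
              f"diverticulitis={a.diverticulitis.value}")

# Patient A is a case only for the text algorithm (never coded); patient B is
# a diverticulitis case for the structured and comparator algorithms; patient
# C is a control everywhere.
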
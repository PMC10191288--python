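"""File formats: reports JSONL, event/covariate TSVs, and minimal VCF.

Conventions honoured throughout the package: dates are ISO-8601, genomic
positions are 1-based (VCF), text offsets are 0-based half-open, TSVs are
tab-separated UTF-8 with a header row and "NA" for missing.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import date, datetime
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .association import GenotypeMatrix, Variant
from .clinical_text import ReportDocument
from .phenotyping import (
    Algorithm,
    CodeEvent,
    PatientRecord,
    PhenotypeAssignment,
    ProcedureEvent,
    Status,
)

NA = "NA"


def _parse_date(s: str) -> date:
    return datetime.strptime(s, "%Y-%m-%d").date()


# --------------------------------------------------------------------------
# reports (JSON-lines)


def write_reports_jsonl(reports: Iterable[ReportDocument], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            fh.write(
                json.dumps(
                    {
                        "patient_id": r.patient_id,
                        "report_type": r.report_type,
                        "report_date": r.report_date.isoformat(),
                        "text": r.text,
                    }
                )
                + "\n"
            )


def read_reports_jsonl(path) -> list[ReportDocument]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(
                ReportDocument(
                    patient_id=obj["patient_id"],
                    report_type=obj["report_type"],
                    report_date=_parse_date(obj["report_date"]),
                    text=obj["text"],
                )
            )
    return out


# --------------------------------------------------------------------------
# code / procedure / covariate / assignment tables (TSV)


def write_codes_tsv(codes: Iterable[CodeEvent], path) -> None:
    df = pd.DataFrame(
        [(c.patient_id, c.system, c.code, c.date.isoformat()) for c in codes],
        columns=["patient_id", "system", "code", "date"],
    )
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_codes_tsv(path) -> list[CodeEvent]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        CodeEvent(row.patient_id, row.system, row.code, _parse_date(row.date))
        for row in df.itertuples()
    ]


def write_procedures_tsv(procs: Iterable[ProcedureEvent], path) -> None:
    df = pd.DataFrame(
        [(p.patient_id, p.kind, p.date.isoformat()) for p in procs],
        columns=["patient_id", "kind", "date"],
    )
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_procedures_tsv(path) -> list[ProcedureEvent]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [ProcedureEvent(r.patient_id, r.kind, _parse_date(r.date)) for r in df.itertuples()]


def write_covariates_tsv(covariates: pd.DataFrame, path) -> None:
    covariates.to_csv(path, sep="\t", na_rep=NA, index=True)


def read_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])


def write_assignments_tsv(assignments: Iterable[PhenotypeAssignment], path) -> None:
    df = pd.DataFrame(
        [
            (a.patient_id, a.algorithm.value, a.diverticulosis.value, a.diverticulitis.value)
            for a in assignments
        ],
        columns=["patient_id", "algorithm", "diverticulosis", "diverticulitis"],
    )
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_assignments_tsv(path) -> list[PhenotypeAssignment]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        PhenotypeAssignment(
            r.patient_id, Algorithm(r.algorithm), Status(r.diverticulosis), Status(r.diverticulitis)
        )
        for r in df.itertuples()
    ]


def write_gold_labels_tsv(gold: dict[str, tuple[bool, bool]], path) -> None:
    df = pd.DataFrame(
        [(pid, int(o), int(i)) for pid, (o, i) in gold.items()],
        columns=["patient_id", "gold_diverticulosis", "gold_diverticulitis"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_gold_labels_tsv(path) -> dict[str, tuple[bool, bool]]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    return {
        r.patient_id: (bool(r.gold_diverticulosis), bool(r.gold_diverticulitis))
        for r in df.itertuples()
    }


def assemble_records(
    reports: Iterable[ReportDocument],
    codes: Iterable[CodeEvent],
    procedures: Iterable[ProcedureEvent],
    covariates: pd.DataFrame | None = None,
) -> list[PatientRecord]:
    """Group per-stream rows into PatientRecords (sorted by patient id)."""
    records: dict[str, PatientRecord] = {}

    def rec(pid: str) -> PatientRecord:
        if pid not in records:
            records[pid] = PatientRecord(patient_id=pid)
        return records[pid]

    for r in reports:
        rec(r.patient_id).reports.append(r)
    for c in codes:
        rec(c.patient_id).codes.append(c)
    for p in procedures:
        rec(p.patient_id).procedures.append(p)
    if covariates is not None:
        for pid, row in covariates.iterrows():
            r = rec(str(pid))
            r.sex = str(row.get("sex", r.sex))
            r.age_at_colonoscopy = float(row.get("age_at_colonoscopy", r.age_at_colonoscopy))
            r.site = str(row.get("site", r.site))
    return [records[k] for k in sorted(records)]


# --------------------------------------------------------------------------
# genotypes (minimal VCF v4.2)

_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated ALT dosage">
"""


def write_vcf(genotypes: GenotypeMatrix, path, dosage_field: bool = True) -> None:
    """Write a minimal uncompressed VCF v4.2 with GT (and optionally DS)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        seen: list[str] = []
        for v in genotypes.variants:
            if v.chrom not in seen:
                seen.append(v.chrom)
        for chrom in seen:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        fmt = "GT:DS" if dosage_field else "GT"
        for j, v in enumerate(genotypes.variants):
            fields = [v.chrom, str(v.pos), v.id, v.ref, v.alt, ".", "PASS", "."]
            cells = []
            for d in genotypes.dosage[:, j]:
                if np.isnan(d):
                    cells.append("./." + (":." if dosage_field else ""))
                    continue
                g = int(round(d))
                gt = ["0/0", "0/1", "1/1"][min(max(g, 0), 2)]
                cells.append(f"{gt}:{d:g}" if dosage_field else gt)
            fh.write("\t".join(fields + [fmt] + cells) + "\n")


class VcfFormatError(ValueError):
    pass


def read_vcf(path) -> tuple[list[Variant], GenotypeMatrix]:
    """Read biallelic SNVs from a VCF into an ALT-dosage matrix.

    GT is converted to 0/1/2 ALT-allele dosage; a DS field, when present,
    takes precedence. Missing genotypes ("./.") become NaN. Multiallelic
    records raise :class:`VcfFormatError`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise VcfFormatError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} ({rec.ID or '.'}) not supported"
            )
        variants.append(
            Variant(
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                ref=rec.REF,
                alt=rec.ALT[0],
            )
        )
        ds = rec.format("DS")
        if ds is not None:
            col = np.array(ds, dtype=float).reshape(-1)
            col[~np.isfinite(col)] = np.nan
        else:
            gts = rec.genotype.array()  # columns: allele1, allele2, phased
            alleles = gts[:, :2].astype(float)
            alleles[alleles < 0] = np.nan
            col = alleles.sum(axis=1)
        columns.append(col)
    vcf.close()
    dosage = (
        np.column_stack(columns) if columns else np.zeros((len(samples), 0))
    )
    return variants, GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def write_phenome_tsv(matrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", na_rep=NA)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
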
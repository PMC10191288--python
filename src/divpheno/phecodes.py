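"""Phecode mapping and the patient x phecode phenome matrix for PheWAS.

Phecodes are dotted-decimal groupings of ICD diagnosis codes with an
implicit hierarchy by decimal truncation (562.11 -> 562.1 -> 562). The
package ships a small synthetic map/definition fixture covering the
diverticular-disease family and its gastrointestinal exclusion codes; the
loaders accept a user-supplied export of the full published map (CSV with
the same columns).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phenotyping import CodeEvent

logger = logging.getLogger(__name__)

CASE, CONTROL, EXCLUDED = 1, 0, -1  # int8 entries of the phenome matrix


@dataclass(frozen=True)
class PhecodeDefinition:
    phecode: str
    label: str
    category: str
    exclusion_ranges: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for lo, hi in self.exclusion_ranges:
            if lo > hi:
                raise ValueError(f"exclusion range [{lo}, {hi}] inverted for {self.phecode}")


def _open_data(name: str):
    return resources.files("divpheno.data").joinpath(name).open("r", encoding="utf-8")


def load_phecode_map(path=None) -> dict[tuple[str, str], str]:
    """Load an (icd_system, icd_code) -> phecode lookup table.

    Defaults to the packaged synthetic fixture; pass a path to use a full
    published map export with columns icd_system, icd_code, phecode.
    """
    fh = _open_data("phecode_map_synthetic.csv") if path is None else open(path, "r", encoding="utf-8")
    with fh:
        return {
            (row["icd_system"], row["icd_code"]): row["phecode"]
            for row in csv.DictReader(fh)
        }


def load_phecode_definitions(path=None) -> dict[str, PhecodeDefinition]:
    fh = (
        _open_data("phecode_definitions_synthetic.csv")
        if path is None
        else open(path, "r", encoding="utf-8")
    )
    defs = {}
    with fh:
        for row in csv.DictReader(fh):
            ranges = ()
            if row.get("exclusion_range_low") not in (None, "", "NA"):
                ranges = ((float(row["exclusion_range_low"]), float(row["exclusion_range_high"])),)
            defs[row["phecode"]] = PhecodeDefinition(
                row["phecode"], row["label"], row["category"], ranges
            )
    return defs


def phecode_ancestors(phecode: str) -> list[str]:
    """Ancestors by decimal truncation: '562.11' -> ['562.1', '562']."""
    integer, _, frac = phecode.partition(".")
    return [integer + ("." + frac[:k] if k else "") for k in range(len(frac) - 1, -1, -1)]


def map_icd_to_phecode(
    event: CodeEvent, phecode_map: Mapping[tuple[str, str], str]
) -> list[str]:
    """Phecodes for one coded event: the mapped code plus all its ancestors.

    Exact-match lookup on the dot-normalized ICD code; unmapped codes yield
    an empty list, malformed codes are skipped with a warning.
    """
    code = event.code.strip()
    if not code:
        logger.warning("skipping malformed (empty) code for patient %s", event.patient_id)
        return []
    phecode = phecode_map.get((event.system, code))
    if phecode is None:
        return []
    return [phecode] + phecode_ancestors(phecode)


@dataclass
class PhenomeMatrix:
    """Patient x phecode case/control/excluded statuses (int8 DataFrame)."""

    status: pd.DataFrame  # index: patient ids; columns: phecodes; values CASE/CONTROL/EXCLUDED
    definitions: dict[str, PhecodeDefinition]

    @property
    def patients(self) -> list[str]:
        return list(self.status.index)

    @property
    def phecodes(self) -> list[str]:
        return list(self.status.columns)

    def case_counts(self) -> pd.Series:
        return (self.status == CASE).sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Export with values 1/0/NA for case/control/excluded."""
        out = self.status.astype("object").copy()
        return out.mask(self.status == EXCLUDED, other=pd.NA)


def build_phenome(
    events: Iterable[CodeEvent],
    phecode_map: Mapping[tuple[str, str], str],
    definitions: Mapping[str, PhecodeDefinition],
    patients: Sequence[str] | None = None,
    min_code_count: int = 1,
) -> PhenomeMatrix:
    """Build the unfiltered phenome matrix from coded diagnosis events.

    A patient is a case for phecode P when at least ``min_code_count``
    events map to P (directly or through the hierarchy); a non-case is
    excluded for P when any of their events maps into P's exclusion ranges;
    otherwise control. Event order never matters.
    """
    events = list(events)
    phecodes = sorted(definitions, key=_phecode_sort_key)
    col_idx = {p: j for j, p in enumerate(phecodes)}
    if patients is None:
        patients = sorted({ev.patient_id for ev in events})
    row_idx = {p: i for i, p in enumerate(patients)}
    counts = np.zeros((len(patients), len(phecodes)), dtype=np.int32)
    patient_phecode_values: dict[str, set[float]] = {p: set() for p in patients}
    for ev in events:
        if ev.patient_id not in row_idx:
            continue
        mapped = map_icd_to_phecode(ev, phecode_map)
        for p in mapped:
            if p in col_idx:
                counts[row_idx[ev.patient_id], col_idx[p]] += 1
        if mapped:
            patient_phecode_values[ev.patient_id].add(float(mapped[0]))
    status = np.full(counts.shape, CONTROL, dtype=np.int8)
    status[counts >= min_code_count] = CASE
    for j, phe in enumerate(phecodes):
        ranges = definitions[phe].exclusion_ranges
        if not ranges:
            continue
        for pid, values in patient_phecode_values.items():
            i = row_idx[pid]
            if status[i, j] != CASE and any(
                lo <= v <= hi for v in values for lo, hi in ranges
            ):
                status[i, j] = EXCLUDED
    frame = pd.DataFrame(status, index=list(patients), columns=phecodes)
    return PhenomeMatrix(frame, dict(definitions))


def filter_phenome(matrix: PhenomeMatrix, min_cases: int = 30) -> PhenomeMatrix:
    """Drop phecode columns with fewer than ``min_cases`` cases (>= kept)."""
    keep = matrix.case_counts() >= min_cases
    kept_codes = [p for p in matrix.phecodes if keep[p]]
    if not kept_codes:
        logger.warning("filter_phenome: every phecode column dropped (min_cases=%d)", min_cases)
    return PhenomeMatrix(
        matrix.status[kept_codes].copy(),
        {p: d for p, d in matrix.definitions.items() if p in kept_codes},
    )


def _phecode_sort_key(code: str) -> float:
    try:
        return float(code)
    except ValueError:  # pragma: no cover - definitions validate upstream
        return float("inf")
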
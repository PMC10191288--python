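"""End-to-end pipeline: simulate -> phenotype -> validate/compare -> gwas
-> prune -> phewas -> power, with a reproducibility manifest.

Each stage writes its artifact into the output directory; the manifest
records the seed, configuration hash, package version and per-stage row
counts so a run can be reproduced bit-for-bit from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    PowerParams,
    gwas_power,
    min_n,
    run_gwas,
    run_phewas,
    select_independent_hits,
)
from .io import (
    ensure_dir,
    write_assignments_tsv,
    write_codes_tsv,
    write_covariates_tsv,
    write_phenome_tsv,
    write_procedures_tsv,
    write_reports_jsonl,
    write_vcf,
)
from .phecodes import build_phenome, filter_phenome, load_phecode_definitions, load_phecode_map
from .phenotyping import (
    Algorithm,
    case_ids,
    classify_cohort,
    compare_algorithms,
    compute_ppv,
)
from .synthetic import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    out_dir: str = "divpheno_run"
    seed: int = 17
    n_patients: int = 2000
    window_days: int = 7
    p_thresh: float = 1e-6
    r2_thresh: float = 0.1
    q: float = 0.05
    min_cases: int = 30
    power_eaf: float = 0.18
    power_prevalence: float = 0.10
    power_or: float = 1.20
    power_alpha: float = 5e-8
    power_target: float = 0.80
    power_case_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.q < 1 and 0 < self.p_thresh < 1 and 0 <= self.r2_thresh <= 1):
            raise ValueError("thresholds out of range")
        if self.min_cases < 0 or self.window_days < 0:
            raise ValueError("min_cases and window_days must be non-negative")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a simulated cohort; returns the manifest dict."""
    out = ensure_dir(config.out_dir)
    manifest: dict = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return result

        return wrap

    # -- simulate
    sim_cfg = SimulationConfig(n_patients=config.n_patients, seed=config.seed)
    records, truth = stage("simulate")(lambda: simulate_cohort(sim_cfg))
    write_reports_jsonl([r for rec in records for r in rec.reports], out / "notes.jsonl")
    write_codes_tsv([c for rec in records for c in rec.codes], out / "codes.tsv")
    write_procedures_tsv([p for rec in records for p in rec.procedures], out / "procedures.tsv")
    write_covariates_tsv(truth.covariates(), out / "covariates.tsv")
    write_vcf(truth.genotypes, out / "genotypes.vcf")
    truth.table.to_csv(out / "truth.tsv", sep="\t")
    manifest["stages"]["simulate"] = {"n_patients": len(records)}

    # -- phenotype (all three algorithms)
    phecode_map = load_phecode_map()
    assignments = {}
    for algo in Algorithm:
        assignments[algo] = stage(f"phenotype:{algo.value}")(
            lambda a=algo: classify_cohort(
                records, a, phecode_map=phecode_map, window_days=config.window_days
            )
        )
        write_assignments_tsv(assignments[algo], out / f"assignments_{algo.value}.tsv")
    manifest["stages"]["phenotype"] = {
        algo.value: len(asn) for algo, asn in assignments.items()
    }

    # -- validate against simulated truth (chart review stand-in)
    gold = {pid: bool(v) for pid, v in truth.table["true_diverticulosis"].items()}
    validation = stage("validate")(lambda: compute_ppv(assignments[Algorithm.NLP], gold))
    manifest["stages"]["validate"] = dataclasses.asdict(validation)

    # -- compare NLP vs ICD comparator
    comparison = stage("compare")(
        lambda: compare_algorithms(
            case_ids(assignments[Algorithm.NLP], "diverticulosis"),
            case_ids(assignments[Algorithm.ICD_COMPARATOR], "diverticulosis"),
        )
    )
    manifest["stages"]["compare"] = dataclasses.asdict(comparison)

    # -- gwas on diverticulosis
    cov = truth.covariates()
    results = stage("gwas")(
        lambda: run_gwas(truth.genotypes, assignments[Algorithm.NLP], cov, "diverticulosis")
    )
    gwas_df = pd.DataFrame(
        [
            (
                r.variant.id, r.variant.chrom, r.variant.pos, r.beta, r.se,
                r.odds_ratio, r.p, r.n, r.n_case, r.eaf, r.converged,
            )
            for r in results
        ],
        columns=["id", "chrom", "pos", "beta", "se", "or", "p", "n", "n_case", "eaf", "converged"],
    )
    gwas_df.to_csv(out / "gwas.tsv", sep="\t", index=False)
    manifest["stages"]["gwas"] = {"n_variants": len(results)}

    # -- prune
    hits = stage("prune")(
        lambda: select_independent_hits(results, truth.genotypes, config.p_thresh, config.r2_thresh)
    )
    (out / "hits.tsv").write_text(
        "id\tchrom\tpos\n" + "".join(f"{v.id}\t{v.chrom}\t{v.pos}\n" for v in hits)
    )
    manifest["stages"]["prune"] = {"n_hits": len(hits)}

    # -- phewas for the top variant (or the first variant if none suggestive)
    definitions = load_phecode_definitions()
    all_codes = [c for rec in records for c in rec.codes]
    phenome = stage("phenome")(
        lambda: filter_phenome(
            build_phenome(all_codes, phecode_map, definitions, patients=list(truth.table.index)),
            config.min_cases,
        )
    )
    write_phenome_tsv(phenome, out / "phenome.tsv")
    phewas_rows = []
    if phenome.phecodes and truth.genotypes.variants:
        target = hits[0].id if hits else truth.genotypes.variants[0].id
        j = next(i for i, v in enumerate(truth.genotypes.variants) if v.id == target)
        phewas_rows = stage("phewas")(
            lambda: run_phewas(
                truth.genotypes.column(j), truth.genotypes.samples, phenome, cov, config.q
            )
        )
        pd.DataFrame(
            [
                (r.phecode, r.label, r.category, r.result.odds_ratio, r.result.p,
                 r.q_adjusted, r.fdr_significant, r.result.n, r.result.n_case)
                for r in phewas_rows
            ],
            columns=["phecode", "label", "category", "or", "p", "q_adjusted",
                     "fdr_significant", "n", "n_case"],
        ).to_csv(out / "phewas.tsv", sep="\t", index=False)
    manifest["stages"]["phewas"] = {"n_phecodes": len(phewas_rows)}

    # -- power
    params = PowerParams(
        eaf=config.power_eaf,
        prevalence=config.power_prevalence,
        odds_ratio=config.power_or,
        alpha=config.power_alpha,
        power=config.power_target,
        case_fraction=config.power_case_fraction,
    )
    n_required = stage("power")(lambda: min_n(params))
    manifest["stages"]["power"] = {
        "min_n": n_required,
        "power_at_min_n": gwas_power(params, n_required),
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
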
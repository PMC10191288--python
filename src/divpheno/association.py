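"""Covariate-adjusted logistic association testing and the power calculator.

The core fitter is a hand-written iteratively reweighted least squares
(IRLS) maximum-likelihood routine with explicit convergence and separation
contracts, so that every downstream consumer (GWAS, PheWAS) shares one
numeric behaviour. Standard errors come from the observed information at
the optimum; p-values are two-sided Wald by default, with a likelihood-
ratio test available behind a flag.

Also here: greedy LD (r^2) pruning of suggestive hits, Benjamini-Hochberg
FDR, and an allelic case-control GWAS power calculator under Hardy-
Weinberg genotype frequencies and a log-additive odds model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .phecodes import CASE, EXCLUDED, PhenomeMatrix
from .phenotyping import PhenotypeAssignment, Status

logger = logging.getLogger(__name__)

COVARIATE_PC_COLUMNS = [f"PC{i}" for i in range(1, 11)]


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    eaf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class GenotypeMatrix:
    """n samples x m variants additive ALT-dosage matrix (NaN = missing)."""

    samples: list[str]
    variants: list[Variant]
    dosage: np.ndarray  # float (n, m), values in [0, 2] or NaN

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage shape mismatch")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosage, initial=0) < 0 or np.nanmax(self.dosage, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    def column(self, j: int) -> np.ndarray:
        return self.dosage[:, j]


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    converged: bool
    separated: bool
    loglik: float
    n_iter: int


@dataclass
class AssociationResult:
    variant: Variant | None
    phecode: str | None
    beta: float
    se: float
    odds_ratio: float
    p: float
    n: int
    n_case: int
    eaf: float
    converged: bool


@dataclass
class PhewasRow:
    phecode: str
    label: str
    category: str
    result: AssociationResult
    q_adjusted: float | None
    fdr_significant: bool


@dataclass(frozen=True)
class PowerParams:
    eaf: float
    prevalence: float
    odds_ratio: float
    alpha: float = 5e-8
    power: float = 0.80
    case_fraction: float = 0.10
    model: str = "allelic"

    def __post_init__(self) -> None:
        checks = {
            "eaf": self.eaf,
            "prevalence": self.prevalence,
            "alpha": self.alpha,
            "power": self.power,
            "case_fraction": self.case_fraction,
        }
        for name, value in checks.items():
            if not 0 < value < 1:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {value}")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    column_names: Sequence[str] | None = None,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
    separation_beta: float = 15.0,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    Converges when the maximum absolute score drops below ``score_tol`` or
    the relative log-likelihood change drops below ``ll_tol`` (cap
    ``max_iter`` iterations). Complete or quasi-complete separation is
    flagged (not raised) as non-convergence with any ``|beta| >
    separation_beta``. A rank-deficient design raises
    :class:`RankDeficientError` naming the offending columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be (n, k) and y must be (n,)")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    _check_rank(X, column_names)
    n, k = X.shape
    beta = np.zeros(k)
    const_cols = np.flatnonzero(np.ptp(X, axis=0) == 0)
    if const_cols.size and 0 < y.mean() < 1:
        beta[const_cols[0]] = np.log(y.mean() / (1 - y.mean())) / X[0, const_cols[0]]
    ll = _loglik(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        w = np.clip(mu * (1 - mu), 1e-12, None)
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, score, rcond=None)[0]
        # step-halving keeps the likelihood monotone
        new_ll = _loglik(X, y, beta + step)
        halvings = 0
        while new_ll < ll and halvings < 20:
            step *= 0.5
            new_ll = _loglik(X, y, beta + step)
            halvings += 1
        beta = beta + step
        if abs(new_ll - ll) < ll_tol * (abs(ll) + 1e-12):
            ll = new_ll
            mu = expit(X @ beta)
            converged = np.max(np.abs(X.T @ (y - mu))) < np.sqrt(score_tol)
            break
        ll = new_ll
    mu = expit(X @ beta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    hess = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    # under complete/quasi-complete separation the score also vanishes as
    # |beta| -> inf, so an extreme coefficient overrides apparent convergence
    separated = bool(np.any(np.abs(beta) > separation_beta))
    if separated:
        converged = False
    return LogisticFit(beta, se, converged, separated, _loglik(X, y, beta), it)


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _check_rank(X: np.ndarray, column_names: Sequence[str] | None) -> None:
    n, k = X.shape
    if n < k:
        raise RankDeficientError(f"more columns ({k}) than rows ({n})")
    _, rmat = np.linalg.qr(X)
    diag = np.abs(np.diag(rmat))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = np.flatnonzero(diag <= tol)
    if bad.size:
        names = (
            [column_names[int(j)] for j in bad]
            if column_names is not None
            else [f"column {int(j)}" for j in bad]
        )
        raise RankDeficientError(f"design matrix rank deficient; collinear columns: {names}")


def wald_p(beta: float, se: float) -> float:
    if not np.isfinite(se) or se <= 0:
        return 1.0
    z = beta / se
    return float(min(1.0, max(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1))))


def build_covariate_design(
    covariates: pd.DataFrame,
    include: Sequence[str] = ("sex", "age_at_colonoscopy", "site") + tuple(COVARIATE_PC_COLUMNS),
) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate design; site one-hot with the alphabetically
    first site as reference, sex coded F=0/M=1."""
    cols: list[np.ndarray] = [np.ones(len(covariates))]
    names = ["intercept"]
    for name in include:
        if name not in covariates.columns and name != "site":
            raise KeyError(f"missing covariate column: {name}")
        if name == "sex":
            cols.append((covariates["sex"].astype(str) == "M").to_numpy(dtype=float))
            names.append("sex_M")
        elif name == "site":
            if "site" not in covariates.columns:
                raise KeyError("missing covariate column: site")
            sites = sorted(covariates["site"].astype(str).unique())
            for s in sites[1:]:
                cols.append((covariates["site"].astype(str) == s).to_numpy(dtype=float))
                names.append(f"site_{s}")
        else:
            vals = pd.to_numeric(covariates[name], errors="coerce")
            if vals.isna().any():
                raise ValueError(f"missing values in covariate {name}")
            cols.append(vals.to_numpy(dtype=float))
            names.append(name)
    return np.column_stack(cols), names


def outcome_from_assignments(
    assignments: Iterable[PhenotypeAssignment], analysis: str
) -> dict[str, int]:
    """Binary GWAS outcome per patient id.

    ``analysis='diverticulosis'``: cases are diverticulosis cases (with or
    without diverticulitis) vs controls. ``analysis='diverticulitis'``:
    cases are diverticulitis cases vs controls; diverticulosis-only
    patients are dropped from the analysis entirely.
    """
    y: dict[str, int] = {}
    for a in assignments:
        if analysis == "diverticulosis":
            if a.diverticulosis is Status.CASE:
                y[a.patient_id] = 1
            elif a.diverticulosis is Status.CONTROL:
                y[a.patient_id] = 0
        elif analysis == "diverticulitis":
            if a.diverticulitis is Status.CASE:
                y[a.patient_id] = 1
            elif a.diverticulosis is Status.CONTROL and a.diverticulitis is Status.CONTROL:
                y[a.patient_id] = 0
            # diverticulosis-only patients dropped
        else:
            raise ValueError(f"unknown analysis {analysis!r}")
    return y


def run_gwas(
    genotypes: GenotypeMatrix,
    assignments: Iterable[PhenotypeAssignment] | Mapping[str, int],
    covariates: pd.DataFrame,
    analysis: str = "diverticulosis",
    covariate_columns: Sequence[str] = ("sex", "age_at_colonoscopy", "site") + tuple(COVARIATE_PC_COLUMNS),
) -> list[AssociationResult]:
    """Per-variant covariate-adjusted logistic GWAS (additive dosage model).

    Samples with missing dosage are dropped per variant; monomorphic
    variants are dropped with a logged reason. Results are sorted by
    p-value ascending.
    """
    if isinstance(assignments, Mapping):
        y_by_id = dict(assignments)
    else:
        y_by_id = outcome_from_assignments(assignments, analysis)
    sample_idx = [i for i, s in enumerate(genotypes.samples) if s in y_by_id]
    ids = [genotypes.samples[i] for i in sample_idx]
    if not ids:
        raise ValueError("no overlapping samples between genotypes and outcomes")
    y_all = np.array([y_by_id[s] for s in ids], dtype=float)
    if len(np.unique(y_all)) < 2:
        raise ValueError("need both outcome classes after case/control filtering")
    cov = covariates.set_index("patient_id") if "patient_id" in covariates.columns else covariates
    cov = cov.loc[ids]
    X_cov, cov_names = build_covariate_design(cov, covariate_columns)
    results: list[AssociationResult] = []
    dose_all = genotypes.dosage[sample_idx, :]
    for j, variant in enumerate(genotypes.variants):
        g = dose_all[:, j]
        keep = ~np.isnan(g)
        gk, yk = g[keep], y_all[keep]
        if gk.size < X_cov.shape[1] + 1 or np.ptp(gk) == 0:
            logger.info("dropping variant %s: monomorphic or too few samples", variant.id)
            continue
        if len(np.unique(yk)) < 2:
            logger.info("dropping variant %s: single outcome class after missing-drop", variant.id)
            continue
        X = np.column_stack([X_cov[keep], gk])
        fit = fit_logistic(X, yk, column_names=cov_names + ["dosage"])
        beta, se = fit.beta[-1], fit.se[-1]
        results.append(
            AssociationResult(
                variant=variant,
                phecode=None,
                beta=float(beta),
                se=float(se),
                odds_ratio=float(np.exp(beta)),
                p=wald_p(beta, se) if fit.converged else 1.0,
                n=int(gk.size),
                n_case=int(yk.sum()),
                eaf=float(gk.mean() / 2.0),
                converged=fit.converged and not fit.separated,
            )
        )
    results.sort(key=lambda r: (r.p, r.variant.chrom, r.variant.pos))
    return results


def genotype_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over jointly non-missing samples.

    Zero variance in either vector is treated as r^2 = 1 (conservative for
    pruning: the degenerate variant never survives alongside another).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    keep = ~(np.isnan(g1) | np.isnan(g2))
    if keep.sum() < 2:
        raise ValueError("need at least 2 jointly non-missing samples")
    a, b = g1[keep], g2[keep]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 1.0
    r = np.corrcoef(a, b)[0, 1]
    return float(min(1.0, r * r))


def select_independent_hits(
    results: Sequence[AssociationResult],
    genotypes: GenotypeMatrix,
    p_thresh: float = 1e-6,
    r2_thresh: float = 0.1,
) -> list[Variant]:
    """Greedy LD pruning of suggestive hits.

    Candidates with p < ``p_thresh`` are visited in ascending p (ties by
    chrom, pos); each is kept iff its r^2 against every already-kept
    variant is below ``r2_thresh``.
    """
    col = {v.id: j for j, v in enumerate(genotypes.variants)}
    candidates = sorted(
        (r for r in results if r.p < p_thresh and r.variant is not None),
        key=lambda r: (r.p, r.variant.chrom, r.variant.pos),
    )
    kept: list[Variant] = []
    for cand in candidates:
        g = genotypes.column(col[cand.variant.id])
        if all(genotype_r2(g, genotypes.column(col[k.id])) < r2_thresh for k in kept):
            kept.append(cand.variant)
    return kept


def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (rejected flags, adjusted p-values). Rejection: with sorted
    p(1) <= ... <= p(m), find the largest k with p(k) <= k q / m and
    reject all ranks <= k. Adjusted value at rank i is
    min_{j >= i} m p(j) / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj_sorted = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    passing = np.flatnonzero(ranked <= np.arange(1, m + 1) * q / m)
    k = passing[-1] + 1 if passing.size else 0
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:k] = True
    reject = np.zeros(m, dtype=bool)
    adjusted = np.zeros(m)
    reject[order] = reject_sorted
    adjusted[order] = adj_sorted
    return reject, adjusted


def run_phewas(
    snp_dosage: np.ndarray,
    sample_ids: Sequence[str],
    phenome: PhenomeMatrix,
    covariates: pd.DataFrame,
    q: float = 0.05,
    covariate_columns: Sequence[str] = ("site",) + tuple(COVARIATE_PC_COLUMNS),
) -> list[PhewasRow]:
    """Phenome-wide association of one SNP against every phecode column.

    Per phecode: cases=1, controls=0, excluded dropped; model = dosage +
    principal components + site (the default mirrors a PC/site-adjusted
    PheWAS; sex/age can be added via ``covariate_columns``). BH-FDR flags
    are computed across the converged phecodes for this SNP; rows are
    sorted by p.
    """
    dose = np.asarray(snp_dosage, dtype=float)
    ids = list(sample_ids)
    common = [s for s in phenome.patients if s in set(ids)]
    dose_by_id = dict(zip(ids, dose))
    cov = covariates.set_index("patient_id") if "patient_id" in covariates.columns else covariates
    cov = cov.loc[common]
    rows: list[PhewasRow] = []
    base_dose = np.array([dose_by_id[s] for s in common])
    X_cov, cov_names = build_covariate_design(cov, covariate_columns)
    for phe in phenome.phecodes:
        col = phenome.status[phe].loc[common].to_numpy()
        keep = (col != EXCLUDED) & ~np.isnan(base_dose)
        yk = (col[keep] == CASE).astype(float)
        gk = base_dose[keep]
        defn = phenome.definitions[phe]
        if len(np.unique(yk)) < 2 or np.ptp(gk) == 0:
            continue
        X = np.column_stack([X_cov[keep], gk])
        fit = fit_logistic(X, yk, column_names=cov_names + ["dosage"])
        beta, se = fit.beta[-1], fit.se[-1]
        converged = fit.converged and not fit.separated
        res = AssociationResult(
            variant=None,
            phecode=phe,
            beta=float(beta),
            se=float(se),
            odds_ratio=float(np.exp(beta)),
            p=wald_p(beta, se) if converged else 1.0,
            n=int(yk.size),
            n_case=int(yk.sum()),
            eaf=float(gk.mean() / 2.0),
            converged=converged,
        )
        rows.append(PhewasRow(phe, defn.label, defn.category, res, None, False))
    conv = [r for r in rows if r.result.converged]
    if conv:
        reject, adjusted = bh_fdr([r.result.p for r in conv], q)
        for r, rej, adj in zip(conv, reject, adjusted):
            r.fdr_significant = bool(rej)
            r.q_adjusted = float(adj)
    rows.sort(key=lambda r: (r.result.p, r.phecode))
    return rows


# ---------------------------------------------------------------------------
# power calculation


def _case_control_allele_freqs(params: PowerParams) -> tuple[float, float]:
    """Expected effect-allele frequencies in cases and controls.

    Genotype frequencies follow Hardy-Weinberg for the effect-allele
    frequency; per-genotype penetrances follow a log-additive odds model
    whose intercept is solved so the population prevalence matches.
    """
    p = params.eaf
    geno_freq = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])  # 0,1,2 copies
    log_or = np.log(params.odds_ratio)
    g = np.array([0.0, 1.0, 2.0])

    def mean_penetrance(b0: float) -> float:
        return float(geno_freq @ expit(b0 + g * log_or))

    lo, hi = -60.0, 60.0
    if not mean_penetrance(lo) < params.prevalence < mean_penetrance(hi):
        raise ValueError("no valid intercept: degenerate penetrance model")
    b0 = optimize.brentq(lambda b: mean_penetrance(b) - params.prevalence, lo, hi, xtol=1e-12)
    pen = expit(b0 + g * log_or)
    p_case = float(geno_freq @ (pen * g)) / (2 * params.prevalence)
    p_ctrl = float(geno_freq @ ((1 - pen) * g)) / (2 * (1 - params.prevalence))
    return p_case, p_ctrl


def gwas_power(params: PowerParams, n_total: float) -> float:
    """Power of the two-sided allelic (allele-count) test at total sample size n.

    Two-sample z-test comparing effect-allele frequencies between cases and
    controls (2 alleles per subject), normal approximation, critical value
    from the pooled null standard error.
    """
    if params.model != "allelic":
        raise ValueError(f"unsupported power model {params.model!r}")
    p_case, p_ctrl = _case_control_allele_freqs(params)
    n_case = params.case_fraction * n_total
    n_ctrl = (1 - params.case_fraction) * n_total
    if n_case < 1 or n_ctrl < 1:
        return 0.0
    a_case, a_ctrl = 2 * n_case, 2 * n_ctrl  # allele counts
    pbar = (a_case * p_case + a_ctrl * p_ctrl) / (a_case + a_ctrl)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / a_case + 1 / a_ctrl))
    se1 = np.sqrt(p_case * (1 - p_case) / a_case + p_ctrl * (1 - p_ctrl) / a_ctrl)
    d = p_case - p_ctrl
    z_crit = stats.norm.isf(params.alpha / 2)
    power = stats.norm.sf((z_crit * se0 - d) / se1) + stats.norm.cdf((-z_crit * se0 - d) / se1)
    return float(np.clip(power, 0.0, 1.0))


def min_n(params: PowerParams, n_ceiling: int = 100_000_000) -> int:
    """Smallest total sample size reaching the target power (bisection)."""
    target = params.power
    lo, hi = 2, 4
    while gwas_power(params, hi) < target:
        hi *= 2
        if hi > n_ceiling:
            raise ValueError(f"target power unreachable below n = {n_ceiling}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if gwas_power(params, mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi


def min_n_rounded(params: PowerParams, nearest: int = 1000) -> int:
    """Reporting helper: minimum n rounded to the nearest ``nearest``."""
    n = min_n(params)
    return int(round(n / nearest) * nearest)
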
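"""Logistic fitting, FDR, LD pruning, PheWAS and power-calculator tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from divpheno.association import (
    GenotypeMatrix,
    PowerParams,
    RankDeficientError,
    Variant,
    AssociationResult,
    bh_fdr,
    fit_logistic,
    genotype_r2,
    gwas_power,
    min_n,
    min_n_rounded,
    run_phewas,
    select_independent_hits,
)

from oracles import bh_enumerate, grid_search_logistic, prune_oracle


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 30 + [0.0] * 70)
        X = np.ones((100, 1))
        fit = fit_logistic(X, y)
        assert fit.converged
        assert fit.beta[0] == pytest.approx(np.log(30 / 70), abs=1e-8)

    def test_two_by_two_odds_ratio_closed_form(self):
        # saturated 2x2: exp(beta1) = ad / bc
        a, b, c, d = 40, 25, 15, 30  # exposed case, exposed ctrl, unexp case, unexp ctrl
        x = np.array([1.0] * (a + b) + [0.0] * (c + d))
        y = np.array([1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d)
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_logistic(X, y)
        assert np.exp(fit.beta[1]) == pytest.approx(a * d / (b * c), abs=1e-8)

    def test_separation_flagged_not_raised(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        X = np.column_stack([np.ones(20), x])
        fit = fit_logistic(X, x.copy())  # exposure perfectly predicts outcome
        assert not fit.converged and fit.separated

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(50), np.arange(50.0), 2 * np.arange(50.0)])
        y = (np.arange(50) % 2).astype(float)
        with pytest.raises(RankDeficientError, match="x2"):
            fit_logistic(X, y, column_names=["intercept", "x1", "x2"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        beta_true = np.array([-0.3, 0.5, -0.8, 0.2])
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta_true)))).astype(float)
        fit = fit_logistic(X, y)
        oracle = grid_search_logistic(X, y)
        assert np.allclose(fit.beta, oracle, atol=1e-4)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(300), rng.standard_normal((300, 2))])
        y = (rng.random(300) < 0.4).astype(float)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.beta, ref.params, atol=1e-6)
        assert np.allclose(fit.se, ref.bse, rtol=1e-4)


class TestBhFdr:
    @pytest.mark.parametrize(
        "pvals, q, expected_rejects",
        [
            ([0.01, 0.02, 0.03, 0.04], 0.05, 4),
            ([1.0, 1.0], 0.05, 0),
            ([0.04], 0.05, 1),
        ],
    )
    def test_examples(self, pvals, q, expected_rejects):
        reject, _ = bh_fdr(pvals, q)
        assert int(reject.sum()) == expected_rejects

    def test_equals_enumeration_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            p = np.clip(p, 1e-12, 1.0)
            q = float(rng.uniform(0.01, 0.2))
            reject, adjusted = bh_fdr(p, q)
            reject_o, adjusted_o = bh_enumerate(p, q)
            assert np.array_equal(reject, reject_o)
            assert np.allclose(adjusted, adjusted_o, atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = np.clip(rng.random(200) ** 2, 1e-12, 1)
        reject, adjusted = bh_fdr(p, 0.05)
        ref_reject, ref_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.array_equal(reject, ref_reject)
        assert np.allclose(adjusted, ref_adj)

    def test_empty_input(self):
        reject, adjusted = bh_fdr([], 0.05)
        assert reject.size == 0 and adjusted.size == 0


class TestGenotypeR2:
    def test_identical_and_flipped(self):
        g = np.array([0.0, 1, 2, 1, 0, 2])
        assert genotype_r2(g, g) == pytest.approx(1.0)
        assert genotype_r2(g, 2 - g) == pytest.approx(1.0)

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(0)
        g1 = rng.binomial(2, 0.3, 10000).astype(float)
        g2 = rng.binomial(2, 0.3, 10000).astype(float)
        assert genotype_r2(g1, g2) < 0.01

    def test_missing_pairs_dropped(self):
        g1 = np.array([0.0, 1, 2, np.nan, 1])
        g2 = np.array([0.0, 1, 2, 0, np.nan])
        assert genotype_r2(g1, g2) == pytest.approx(1.0)

    def test_zero_variance_is_conservative_one(self):
        assert genotype_r2(np.ones(5), np.array([0.0, 1, 2, 1, 0])) == 1.0


def _geno(dosages):
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    variants = [Variant("1", 100 + j, f"v{j}", "A", "G") for j in range(m)]
    return GenotypeMatrix([f"S{i}" for i in range(n)], variants, dosages)


def _results(genotypes, pvals):
    return [
        AssociationResult(v, None, 0.1, 0.05, 1.1, p, genotypes.dosage.shape[0], 10, 0.3, True)
        for v, p in zip(genotypes.variants, pvals)
    ]


class TestSelectIndependentHits:
    def test_duplicate_variants_keep_smaller_p(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.4, 50).astype(float)
        geno = _geno(np.column_stack([g, g]))
        hits = select_independent_hits(_results(geno, [1e-8, 1e-7]), geno)
        assert [h.id for h in hits] == ["v0"]

    def test_independent_variants_both_kept(self):
        rng = np.random.default_rng(2)
        geno = _geno(rng.binomial(2, 0.4, (500, 2)).astype(float))
        hits = select_independent_hits(_results(geno, [1e-8, 1e-7]), geno)
        assert len(hits) == 2

    def test_p_threshold_filters(self):
        rng = np.random.default_rng(3)
        geno = _geno(rng.binomial(2, 0.4, (100, 2)).astype(float))
        hits = select_independent_hits(_results(geno, [1e-8, 1e-3]), geno)
        assert [h.id for h in hits] == ["v0"]

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_enumeration_oracle_small_instances(self, seed):
        """Exhaustive check of the greedy defining property for m <= 8."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 9))
        n = 120
        base = rng.binomial(2, 0.4, (n, m)).astype(float)
        # correlate some pairs by copying columns with noise
        for j in range(1, m):
            if rng.random() < 0.5:
                src = int(rng.integers(0, j))
                flip = rng.random(n) < 0.15
                base[:, j] = np.where(flip, rng.binomial(2, 0.4, n), base[:, src])
        geno = _geno(base)
        pvals = 10.0 ** rng.uniform(-10, -7, m)
        results = _results(geno, pvals)
        hits = select_independent_hits(results, geno, p_thresh=1e-6, r2_thresh=0.1)
        r2 = [[genotype_r2(base[:, i], base[:, j]) for j in range(m)] for i in range(m)]
        expected = prune_oracle(pvals, r2, 0.1)
        assert {h.id for h in hits} == {f"v{i}" for i in expected}
        # output must be mutually r2-compatible
        for a, b in itertools.combinations(hits, 2):
            ja, jb = int(a.id[1:]), int(b.id[1:])
            assert r2[ja][jb] < 0.1


class TestPower:
    PARAMS = dict(eaf=0.18, prevalence=0.10, odds_ratio=1.20, alpha=5e-8,
                  power=0.80, case_fraction=0.10)

    def test_null_or_limit_gives_alpha(self):
        p = PowerParams(eaf=0.3, prevalence=0.1, odds_ratio=1.0 + 1e-12, alpha=0.05)
        assert gwas_power(p, 10000) == pytest.approx(0.05, abs=1e-3)

    def test_monotone_in_n_and_or(self):
        grid_n = [2000, 5000, 10000, 20000, 50000]
        powers = [gwas_power(PowerParams(**self.PARAMS), n) for n in grid_n]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        grid_or = [1.05, 1.1, 1.2, 1.4, 1.8]
        powers = [
            gwas_power(PowerParams(**{**self.PARAMS, "odds_ratio": o}), 20000) for o in grid_or
        ]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_balanced_allocation_more_powerful(self):
        lo = gwas_power(PowerParams(**{**self.PARAMS, "case_fraction": 0.05}), 30000)
        hi = gwas_power(PowerParams(**{**self.PARAMS, "case_fraction": 0.5}), 30000)
        assert hi > lo

    def test_min_n_inverse_consistent(self):
        params = PowerParams(**self.PARAMS)
        n = min_n(params)
        assert gwas_power(params, n) >= 0.80
        assert gwas_power(params, n - 1) < 0.80

    def test_min_n_monotone_in_target_power(self):
        p80 = PowerParams(**self.PARAMS)
        p90 = PowerParams(**{**self.PARAMS, "power": 0.90})
        assert min_n(p90) > min_n(p80)

    def test_rounding_helper(self):
        params = PowerParams(**self.PARAMS)
        assert min_n_rounded(params) % 1000 == 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PowerParams(eaf=0.0, prevalence=0.1, odds_ratio=1.2)


class TestRunPhewas:
    def _phenome(self, status_df):
        from divpheno.phecodes import PhenomeMatrix, PhecodeDefinition

        defs = {
            c: PhecodeDefinition(c, f"label {c}", "digestive", ())
            for c in status_df.columns
        }
        return PhenomeMatrix(status_df, defs)

    def test_single_phecode_bh_reduces_to_p_vs_q(self):
        import pandas as pd

        rng = np.random.default_rng(5)
        n = 400
        dose = rng.binomial(2, 0.3, n).astype(float)
        ids = [f"S{i}" for i in range(n)]
        y = rng.random(n) < 0.3
        status = pd.DataFrame({"562.1": np.where(y, 1, 0).astype(np.int8)}, index=ids)
        cov = pd.DataFrame(
            {"site": ["A"] * n, **{f"PC{k}": rng.standard_normal(n) for k in range(1, 11)}},
            index=ids,
        )
        rows = run_phewas(dose, ids, self._phenome(status), cov, q=0.05)
        assert len(rows) == 1
        row = rows[0]
        assert row.fdr_significant == (row.result.p <= 0.05)

    def test_planted_phecode_detected_and_nulls_controlled(self):
        import pandas as pd

        rng = np.random.default_rng(11)
        n = 2500
        n_null = 20
        detected = 0
        reps = 12
        for _ in range(reps):
            dose = rng.binomial(2, 0.3, n).astype(float)
            ids = [f"S{i}" for i in range(n)]
            lp = -2.0 + np.log(2.0) * dose
            planted = rng.random(n) < 1 / (1 + np.exp(-lp))
            cols = {"100": planted.astype(np.int8)}
            for j in range(n_null):
                cols[f"{200 + j}"] = (rng.random(n) < 0.2).astype(np.int8)
            status = pd.DataFrame(cols, index=ids)
            cov = pd.DataFrame(
                {"site": rng.choice(["A", "B"], n),
                 **{f"PC{k}": rng.standard_normal(n) for k in range(1, 11)}},
                index=ids,
            )
            rows = run_phewas(dose, ids, self._phenome(status), cov, q=0.05)
            by_code = {r.phecode: r for r in rows}
            detected += by_code["100"].fdr_significant
        assert detected >= int(0.9 * reps)

    def test_all_null_phenome_fdr_controlled(self):
        import pandas as pd

        rng = np.random.default_rng(21)
        n = 600
        total_flags = 0
        reps = 10
        for _ in range(reps):
            dose = rng.binomial(2, 0.3, n).astype(float)
            ids = [f"S{i}" for i in range(n)]
            status = pd.DataFrame(
                {f"{100 + j}": (rng.random(n) < 0.25).astype(np.int8) for j in range(40)},
                index=ids,
            )
            cov = pd.DataFrame(
                {"site": ["A"] * n, **{f"PC{k}": rng.standard_normal(n) for k in range(1, 11)}},
                index=ids,
            )
            rows = run_phewas(dose, ids, self._phenome(status), cov, q=0.05)
            total_flags += sum(r.fdr_significant for r in rows)
        assert total_flags / reps <= 5.0
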
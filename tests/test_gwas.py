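"""GWAS orchestration: residualization, q-values, thresholds, overlap
permutation (vs hypergeometric oracle), covariate scans."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microgwas.gwas import (
    build_covariate_design,
    covariate_association_scan,
    herit_gwas_overlap_test,
    ols_sex_scan,
    overlap_hypergeom,
    qvalues,
    residualize,
    run_gwas,
    study_bonferroni,
)
from microgwas.io import CovariateTable, KinshipMatrix

from conftest import block_chol, block_kinship


class TestResidualize:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = 50
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
            y = rng.normal(size=n)
            got = residualize(y, X)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(got, y - X @ beta, atol=1e-10)
            assert np.abs(X.T @ got).max() < 1e-8

    def test_orthogonal_covariate_returns_centered_y(self):
        rng = np.random.default_rng(1)
        n = 40
        y = rng.normal(size=n)
        x = rng.normal(size=n)
        yc = y - y.mean()
        x -= x.mean()
        x -= (x @ yc) / (yc @ yc) * yc  # orthogonal to centered y
        got = residualize(y, np.column_stack([np.ones(n), x]))
        np.testing.assert_allclose(got, yc, atol=1e-10)

    def test_exact_linear_trait_residuals_zero(self):
        age = np.arange(30, dtype=float)
        y = 2.0 + 0.5 * age
        got = residualize(y, np.column_stack([np.ones(30), age]))
        np.testing.assert_allclose(got, 0.0, atol=1e-10)

    def test_rank_deficient_design_named(self):
        n = 20
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float), 2 * np.arange(n, dtype=float)])
        with pytest.raises(ValueError, match="column"):
            residualize(np.random.default_rng(0).normal(size=n), X)


class TestQvalues:
    def test_bh_closed_form(self):
        q, pi0 = qvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        assert pi0 == 1.0
        np.testing.assert_allclose(q, 0.04, atol=1e-12)

    def test_all_ones(self):
        q, _ = qvalues(np.ones(10))
        np.testing.assert_allclose(q, 1.0)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=500)
        q, _ = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_statsmodels_bh_when_pi0_one(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=80)  # m < 100 -> pi0 = 1 -> exactly BH
        q, _ = qvalues(p)
        _, q_sm, *_ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)

    def test_pi0_near_one_under_null(self):
        rng = np.random.default_rng(4)
        _, pi0 = qvalues(rng.uniform(size=10_000))
        assert 0.9 <= pi0 <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qvalues(np.array([0.5, 1.5]))


class TestStudyBonferroni:
    def test_single_test(self):
        assert study_bonferroni(0.05, [(1, 1)]) == 0.05

    def test_reported_study_threshold(self):
        """(116+3)x211,319 + (104+3)x210,924 + (102+3)x212,153 tests at 0.05."""
        th = study_bonferroni(
            0.05, [(116 + 3, 211_319), (104 + 3, 210_924), (102 + 3, 212_153)]
        )
        mantissa, exponent = f"{th:e}".split("e")
        assert round(float(mantissa)) == 7 and int(exponent) == -10

    def test_proportionality(self):
        a = study_bonferroni(0.05, [(10, 1000)])
        b = study_bonferroni(0.05, [(10, 1000), (10, 1000)])
        assert a == pytest.approx(2 * b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            study_bonferroni(0.05, [])


class TestRunGwas:
    def test_planted_qtl_recovered(self):
        """1-SD planted effect at n=200 is the top hit (sampled seeds)."""
        from microgwas.synthetic import SimulationConfig, simulate_genotypes

        hits = 0
        n = 300
        for seed in range(10):
            cfg = SimulationConfig(
                n_individuals=n, n_snps=800, n_families=60, family_size=5, seed=seed
            )
            g, Kt = simulate_genotypes(cfg)
            rng = np.random.default_rng(seed + 500)
            causal = (g.maf() - 0.3).abs().idxmin()  # the MAF-0.3 study condition
            x = g.dosages[causal].to_numpy()
            L = block_chol(Kt)
            y = 1.0 * (x - x.mean()) + np.sqrt(0.3) * (L @ rng.standard_normal(n)) \
                + np.sqrt(0.7) * rng.standard_normal(n)
            res = run_gwas(pd.Series(y, index=g.individuals), g, Kt, mode="exact")
            if res.table["p"].idxmin() == causal:
                hits += 1
        assert hits >= 9

    def test_permuted_trait_calibrated(self):
        from microgwas.synthetic import SimulationConfig, simulate_genotypes

        cfg = SimulationConfig(
            n_individuals=200, n_snps=1000, n_families=40, family_size=5, seed=77
        )
        g, Kt = simulate_genotypes(cfg)
        rng = np.random.default_rng(78)
        L = block_chol(Kt)
        y = L @ rng.standard_normal(200) * 0.7 + rng.standard_normal(200) * 0.7
        res = run_gwas(pd.Series(rng.permutation(y), index=g.individuals), g, Kt)
        assert 0.85 <= res.lambda_gc() <= 1.15

    def test_constant_trait_rejected(self, cohort):
        with pytest.raises(ValueError, match="constant"):
            run_gwas(
                pd.Series(np.ones(60), index=cohort["g"].individuals),
                cohort["g"],
                cohort["K"],
            )

    def test_power_guard(self, cohort):
        few = cohort["g"].individuals[:10]
        y = pd.Series(np.random.default_rng(0).normal(size=10), index=few)
        with pytest.raises(ValueError, match="power guard"):
            run_gwas(y, cohort["g"], cohort["K"])


class TestCovariateScan:
    @staticmethod
    def _cov(n, rng):
        return CovariateTable(
            pd.DataFrame(
                {
                    "age": rng.integers(18, 80, n).astype(float),
                    "sex": np.array(["F", "M"])[rng.integers(0, 2, n)],
                    "collection_group": np.array(["g1", "g2", "g3"])[rng.integers(0, 3, n)],
                },
                index=pd.Index([f"ind{i:04d}" for i in range(n)], name="individual"),
            )
        )

    def test_planted_sex_effect_found(self):
        rng = np.random.default_rng(5)
        n = 200
        cov = self._cov(n, rng)
        K = block_kinship(n)
        sex = cov.sex_numeric().to_numpy()
        mat = pd.DataFrame(
            {
                "g__hit": sex * 1.0 + rng.standard_normal(n),
                **{f"g__null{j}": rng.standard_normal(n) for j in range(20)},
            },
            index=cov.individuals,
        )
        out = covariate_association_scan(mat, "sex", cov, K)
        assert out.loc["g__hit", "q"] <= 0.05
        assert out.loc["g__hit", "beta"] > 0

    def test_age_direction(self):
        rng = np.random.default_rng(6)
        n = 150
        cov = self._cov(n, rng)
        K = block_kinship(n)
        age = cov.data["age"].to_numpy()
        mat = pd.DataFrame(
            {"g__age": 0.5 * (age - age.mean()) / age.std() + rng.standard_normal(n) * 0.5},
            index=cov.individuals,
        )
        out = covariate_association_scan(mat, "age", cov, K)
        assert out.loc["g__age", "beta"] > 0
        assert out.loc["g__age", "p"] < 0.01

    def test_no_planted_effects_rarely_significant(self):
        rng = np.random.default_rng(7)
        n = 100
        K = block_kinship(n)
        false_calls = 0
        for rep in range(10):
            cov = self._cov(n, np.random.default_rng(rep))
            mat = pd.DataFrame(
                rng.standard_normal((n, 25)),
                index=cov.individuals,
                columns=[f"g__n{j}" for j in range(25)],
            )
            out = covariate_association_scan(mat, "sex", cov, K)
            false_calls += int((out["q"] <= 0.05).sum() > 0)
        assert false_calls <= 2

    def test_single_sex_rejected(self):
        rng = np.random.default_rng(8)
        cov = self._cov(30, rng)
        cov.data["sex"] = "F"
        mat = pd.DataFrame(
            rng.standard_normal((30, 3)), index=cov.individuals, columns=list("abc")
        )
        with pytest.raises(ValueError, match="single-sex"):
            covariate_association_scan(mat, "sex", cov, block_kinship(30))


class TestOverlapTests:
    def test_disjoint_flags_p_one(self):
        h = [True] * 5 + [False] * 5
        g = [False] * 5 + [True] * 5
        obs, p = herit_gwas_overlap_test(h, g, n_perm=500, seed=0)
        assert obs == 0 and p == 1.0

    def test_matches_hypergeometric_tail(self):
        """5 heritable, 5 hits, 10 taxa, overlap 5: P(X>=5) = 1/252."""
        flags = [True] * 5 + [False] * 5
        obs, p = herit_gwas_overlap_test(flags, flags, n_perm=10_000, seed=1)
        assert obs == 5
        exact = 1 / 252
        mc_se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(p - exact) < 4 * mc_se

    def test_plus_one_option(self):
        flags = [True] * 5 + [False] * 5
        _, p = herit_gwas_overlap_test(flags, flags, n_perm=100, seed=2, plus_one=True)
        assert p >= 1 / 101

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for rep in range(60):
            h = rng.permutation([True] * 4 + [False] * 8)
            g = rng.permutation([True] * 5 + [False] * 7)
            _, p = herit_gwas_overlap_test(h, g, n_perm=400, seed=rep)
            ps.append(p)
        # discrete p-values: conservative check of super-uniformity
        assert np.mean(np.array(ps) <= 0.2) < 0.4

    def test_bad_nperm_rejected(self):
        with pytest.raises(ValueError):
            herit_gwas_overlap_test([True], [True], n_perm=0)


class TestOlsSexScanAndHypergeom:
    def test_hypergeom_closed_form(self):
        # |A|=5, |B|=4, overlap 4 in universe of 10: C(5,4)C(5,0)/C(10,4)
        universe = list(range(10))
        p = overlap_hypergeom(universe[:5], universe[1:5], universe)
        assert p == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_overlap_p_near_one(self):
        p = overlap_hypergeom([0], [9], list(range(10)))
        assert p > 0.85

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_hypergeom([], [], [])

    def test_matches_kinship_scan_without_kinship(self):
        """OLS sex scan ~ LMM scan with K = 0 (t vs LRT agree asymptotically)."""
        rng = np.random.default_rng(9)
        n = 500
        sex = np.array(["F", "M"])[rng.integers(0, 2, n)]
        ids = [f"ind{i:04d}" for i in range(n)]
        cov = CovariateTable(
            pd.DataFrame(
                {
                    "age": rng.integers(20, 70, n).astype(float),
                    "sex": sex,
                    "collection_group": np.array(["g1", "g2"])[rng.integers(0, 2, n)],
                },
                index=pd.Index(ids, name="individual"),
            )
        )
        mat = pd.DataFrame(
            rng.standard_normal((n, 6)),
            index=pd.Index(ids, name="individual"),
            columns=[f"g__t{j}" for j in range(6)],
        )
        mat["g__t0"] += (sex == "M") * 0.4
        K0 = KinshipMatrix(np.zeros((n, n)), ids)
        lmm = covariate_association_scan(mat, "sex", cov, K0)
        # residualize on the same non-sex covariates the LMM scan uses
        W = build_covariate_design(cov, ids, exclude=("sex",))
        mat_resid = mat.apply(lambda col: residualize(col.to_numpy(), W), axis=0)
        ols = ols_sex_scan(mat_resid, pd.Series(sex, index=ids))
        np.testing.assert_allclose(ols["beta"], lmm["beta"], atol=1e-8)
        np.testing.assert_allclose(
            np.log(ols["p"]), np.log(lmm["p"]), rtol=1e-2, atol=0.02
        )


def test_covariate_design_shape_and_encoding():
    rng = np.random.default_rng(10)
    n = 25
    cov = CovariateTable(
        pd.DataFrame(
            {
                "age": rng.integers(20, 60, n).astype(float),
                "sex": np.array(["F", "M"])[rng.integers(0, 2, n)],
                "collection_group": np.array(["a", "b", "c"])[rng.integers(0, 3, n)],
            },
            index=pd.Index([f"i{k}" for k in range(n)], name="individual"),
        )
    )
    X = build_covariate_design(cov, cov.individuals)
    # intercept + age + sex + 2 group dummies
    assert X.shape == (n, 5)
    assert (X[:, 0] == 1).all()
    X_nosex = build_covariate_design(cov, cov.individuals, exclude=("sex",))
    assert X_nosex.shape == (n, 4)
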
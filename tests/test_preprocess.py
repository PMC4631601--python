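"""Preprocessing: subsampling, prevalence, inverse-normal transform,
correlation pruning (vs brute-force oracle), season combining, diversity,
PCA-label QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microgwas.io import TaxaCountTable
from microgwas.preprocess import (
    NormalizedTaxaMatrix,
    alpha_diversity,
    combine_replicates,
    combine_seasons,
    correlation_prune,
    inverse_normal_transform,
    pca_label_qc,
    prevalence_filter,
    relative_abundance,
    subsample_counts,
)


def make_table(counts: np.ndarray, taxa=None, individuals=None, level="genus"):
    n, m = counts.shape
    taxa = taxa or [f"g__t{j}" for j in range(m)]
    individuals = individuals or [f"i{k}" for k in range(n)]
    idx = pd.MultiIndex.from_tuples(
        [(i, "s0", "r0") for i in individuals],
        names=["individual", "season", "replicate"],
    )
    counts_df = pd.DataFrame(counts, index=idx, columns=taxa)
    levels = level if isinstance(level, list) else [level] * m
    tax = pd.DataFrame(
        {"level": levels, "lineage": taxa}, index=pd.Index(taxa, name="taxon")
    )
    return TaxaCountTable(counts_df, tax)


class TestSubsample:
    def test_below_depth_unchanged(self):
        t = make_table(np.array([[100, 200], [10, 20]]))
        out = subsample_counts(t, max_depth=1000, seed=0)
        assert out.counts.equals(t.counts)

    def test_above_depth_exact_and_dominated(self):
        t = make_table(np.array([[3000, 1500]]))
        out = subsample_counts(t, max_depth=2000, seed=0)
        assert out.counts.sum(axis=1).iloc[0] == 2000
        assert (out.counts.to_numpy() <= t.counts.to_numpy()).all()

    def test_hypergeometric_expectation_preserved(self):
        counts = np.array([[600, 300, 100]])
        t = make_table(counts)
        props = []
        for seed in range(500):
            out = subsample_counts(t, max_depth=200, seed=seed)
            props.append(out.counts.to_numpy()[0] / 200)
        mean_prop = np.mean(props, axis=0)
        true_prop = counts[0] / counts.sum()
        # MC SE of the mean proportion over 500 draws
        mc_se = np.std(props, axis=0, ddof=1) / np.sqrt(500)
        assert (np.abs(mean_prop - true_prop) < 3 * mc_se + 1e-12).all()


class TestCombineAndNormalize:
    def test_replicates_summed(self):
        idx = pd.MultiIndex.from_tuples(
            [("i1", "s0", "r0"), ("i1", "s0", "r1")],
            names=["individual", "season", "replicate"],
        )
        counts = pd.DataFrame([[10], [20]], index=idx, columns=["g__a"])
        tax = pd.DataFrame({"level": ["genus"], "lineage": ["g__a"]}, index=["g__a"])
        out = combine_replicates(TaxaCountTable(counts, tax))
        assert out.counts.iloc[0, 0] == 30

    def test_relative_abundance_sums_to_one(self):
        rng = np.random.default_rng(1)
        t = make_table(rng.integers(1, 100, size=(8, 5)))
        rel = relative_abundance(t)
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(rel.iloc[0], t.counts.iloc[0] / t.counts.iloc[0].sum())

    def test_zero_read_individual_excluded_with_warning(self):
        t = make_table(np.array([[10, 20], [0, 0]]))
        with pytest.warns(UserWarning, match="zero total reads"):
            rel = relative_abundance(t)
        assert len(rel) == 1


class TestPrevalence:
    def test_boundary_inclusive(self):
        # present in 3 of 4 -> 0.75 >= 0.75 kept; present in 2 of 4 -> removed
        counts = np.array([[1, 1], [1, 1], [1, 0], [0, 0]])
        out = prevalence_filter(make_table(counts), 0.75)
        assert out.taxa == ["g__t0"]

    def test_matches_recount_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            counts = rng.integers(0, 3, size=(10, 6))
            t = make_table(counts)
            kept = set(prevalence_filter(t, 0.75).taxa)
            expected = {
                f"g__t{j}"
                for j in range(6)
                if (counts[:, j] > 0).sum() / 10 >= 0.75
            }
            assert kept == expected


class TestInverseNormal:
    def test_n3_worked_values(self):
        out = inverse_normal_transform([1.0, 2.0, 3.0])
        # Phi^-1((i - 3/8) / 3.25) for i = 1, 2, 3
        np.testing.assert_allclose(out, [-0.8694, 0.0, 0.8694], atol=5e-5)

    def test_median_of_odd_n_is_zero(self):
        out = inverse_normal_transform([5.0, 1.0, 9.0, 3.0, 7.0])
        assert out[np.argsort([5.0, 1.0, 9.0, 3.0, 7.0])[2] == np.arange(5)][0] == pytest.approx(0.0)

    def test_rank_invariance(self):
        a = inverse_normal_transform(np.array([10.0, 20.0, 35.0, 90.0]))
        b = inverse_normal_transform(np.array([1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_allclose(a, b)

    def test_monotone_in_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        out = inverse_normal_transform(x)
        assert (np.diff(out[np.argsort(x)]) >= 0).all()

    def test_ties_get_average_rank_value(self):
        out = inverse_normal_transform([1.0, 1.0, 2.0])
        assert out[0] == out[1] < out[2]

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            inverse_normal_transform([2.0, 2.0, 2.0])

    def test_ks_against_standard_normal(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(size=200)  # heavily skewed input
        out = inverse_normal_transform(x)
        assert stats.kstest(out, "norm").pvalue > 0.01


def brute_force_prune(matrix, taxonomy, r_threshold=0.9):
    """Independent enumeration oracle for the pruning rules."""
    from microgwas.io import LEVEL_RANK

    alive = list(matrix.columns)
    while True:
        pairs = []
        for i, a in enumerate(sorted(alive)):
            for b in sorted(alive)[i + 1 :]:
                r = matrix[a].corr(matrix[b])
                if r >= r_threshold:
                    pairs.append((r, a, b))
        if not pairs:
            return alive
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        r, a, b = pairs[0]
        ra, rb = LEVEL_RANK[taxonomy.loc[a, "level"]], LEVEL_RANK[taxonomy.loc[b, "level"]]
        if ra != rb:
            removed = a if ra < rb else b
        else:
            removed = min(a, b)
        alive.remove(removed)


class TestCorrelationPrune:
    @staticmethod
    def _frame(cols: dict, levels: dict):
        m = pd.DataFrame(cols)
        tax = pd.DataFrame(
            {"level": [levels[c] for c in m.columns], "lineage": list(m.columns)},
            index=m.columns,
        )
        return m, tax

    def test_cross_level_removes_broader(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=30)
        m, tax = self._frame(
            {"f__fam": g, "g__gen": g}, {"f__fam": "family", "g__gen": "genus"}
        )
        kept, report = correlation_prune(m, tax)
        assert list(kept.columns) == ["g__gen"]
        assert report[0].removed == "f__fam" and report[0].reason == "cross-level"

    def test_same_level_removes_alphabetically_first(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=30)
        m, tax = self._frame({"g__Abc": g, "g__Xyz": g}, {"g__Abc": "genus", "g__Xyz": "genus"})
        kept, report = correlation_prune(m, tax)
        assert list(kept.columns) == ["g__Xyz"]
        assert report[0].removed == "g__Abc"

    def test_below_threshold_kept(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=200)
        noise = rng.normal(size=200)
        # construct a pair with r ~ 0.89 < 0.9
        b = 0.89 * a + np.sqrt(1 - 0.89**2) * noise
        m, tax = self._frame({"g__a": a, "g__b": b}, {"g__a": "genus", "g__b": "genus"})
        assert abs(m["g__a"].corr(m["g__b"])) < 0.9
        kept, report = correlation_prune(m, tax)
        assert len(kept.columns) == 2 and not report

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        levels = ["phylum", "class", "order", "family", "genus"]
        for trial in range(15):
            n_taxa = rng.integers(4, 13)
            base = rng.normal(size=(40, 3))
            cols = {}
            lv = {}
            for j in range(n_taxa):
                name = f"t{rng.integers(0, 1000):03d}_{j}"
                k = rng.integers(0, 3)
                cols[name] = base[:, k] + rng.normal(scale=rng.uniform(0.05, 2.0), size=40)
                lv[name] = levels[rng.integers(0, 5)]
            m, tax = self._frame(cols, lv)
            kept, _ = correlation_prune(m, tax)
            assert list(kept.columns) == [
                c for c in m.columns if c in set(brute_force_prune(m, tax))
            ]


class TestCombineSeasons:
    @staticmethod
    def _matrix(vals: dict, season: str):
        df = pd.DataFrame(vals).T
        df.columns = ["g__a"]
        tax = pd.DataFrame({"level": ["genus"], "lineage": ["g__a"]}, index=["g__a"])
        return NormalizedTaxaMatrix(df, season=season, taxonomy=tax)

    def test_dual_season_mean_and_passthrough(self):
        w = self._matrix({"i1": [1.0], "i2": [0.7]}, "winter")
        s = self._matrix({"i1": [-1.0], "i3": [0.3]}, "summer")
        out = combine_seasons(w, s)
        assert out.values.loc["i1", "g__a"] == 0.0
        assert out.values.loc["i2", "g__a"] == 0.7
        assert out.values.loc["i3", "g__a"] == 0.3

    def test_union_cardinality(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            nw, ns, nb = rng.integers(1, 8, size=3)
            wi = [f"w{i}" for i in range(nw)] + [f"b{i}" for i in range(nb)]
            si = [f"s{i}" for i in range(ns)] + [f"b{i}" for i in range(nb)]
            w = self._matrix({i: [rng.normal()] for i in wi}, "winter")
            s = self._matrix({i: [rng.normal()] for i in si}, "summer")
            out = combine_seasons(w, s)
            assert len(out.values) == nw + ns + nb

    def test_disjoint_taxa_rejected(self):
        w = self._matrix({"i1": [1.0]}, "winter")
        s = self._matrix({"i1": [1.0]}, "summer")
        s.values.columns = ["g__other"]
        with pytest.raises(ValueError, match="common"):
            combine_seasons(w, s)


class TestAlphaDiversity:
    def test_uniform_four_genera(self):
        S, H, J = alpha_diversity([25, 25, 25, 25])
        assert S == 4
        assert H == pytest.approx(np.log(4), abs=1e-12)
        assert J == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_example(self):
        S, H, J = alpha_diversity([10, 10, 20])
        assert S == 3
        assert H == pytest.approx(1.0397, abs=5e-5)
        assert J == pytest.approx(0.9464, abs=5e-5)

    def test_single_genus(self):
        S, H, J = alpha_diversity([0, 42, 0])
        assert S == 1 and H == 0.0 and np.isnan(J)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity([0, 0])

    def test_against_scikit_bio(self):
        from skbio.diversity.alpha import pielou_e, shannon

        rng = np.random.default_rng(4)
        for _ in range(10):
            counts = rng.integers(0, 50, size=12)
            if counts.sum() == 0 or (counts > 0).sum() < 2:
                continue
            S, H, J = alpha_diversity(counts)
            assert H == pytest.approx(float(shannon(counts, base=np.e)), abs=1e-10)
            assert J == pytest.approx(float(pielou_e(counts)), abs=1e-10)


class TestPcaLabelQc:
    def test_planted_label_detected(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(80, 12)))
        out = pca_label_qc(X, X.to_numpy() @ np.ones(12), k=5)
        # the label is a linear combination of the data: some leading PC sees it
        assert out["p"].min() < 1e-4

    def test_pc_orthogonality(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(50, 8)))
        A = X.to_numpy() - X.to_numpy().mean(0)
        U, s, _ = np.linalg.svd(A, full_matrices=False)
        scores = U[:, :5] * s[:5]
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_null_label_calibration(self):
        """Random labels: per-PC rejection rate at alpha=0.05 is ~5%."""
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(60, 10)))
        reject = []
        for _ in range(400):
            lab = rng.integers(0, 2, size=60)
            out = pca_label_qc(X, lab, k=3)
            reject.append((out["p"] < 0.05).to_numpy())
        rate = np.mean(reject, axis=0)
        mc = 3 * np.sqrt(0.05 * 0.95 / 400)
        assert (np.abs(rate - 0.05) < mc + 0.01).all()

    def test_constant_label_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 5)))
        with pytest.raises(ValueError, match="constant"):
            pca_label_qc(X, np.ones(30), k=2)
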
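"""Per-trait GWAS orchestration and multiple-testing machinery.

Each normalized taxon abundance is residualized on age, sex and the
collection-date factor by OLS, then scanned SNP-by-SNP with the mixed-model
LRT of :mod:`microgwas.lmm` using the kinship matrix as the random effect.
Multiple-testing control is applied *within* each GWAS (per-trait Bonferroni
and Storey q-values at 0.1 / 0.2), never pooled across traits; the
study-wise Bonferroni threshold over all trait x SNP tests is reported
separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .genotypes import analysis_maf_filter
from .io import CovariateTable, GenotypeMatrix, KinshipMatrix
from .lmm import eigendecompose_kinship, genomic_control_lambda, lrt_predictor, scan_snps

__all__ = [
    "GwasResult",
    "build_covariate_design",
    "residualize",
    "run_gwas",
    "qvalues",
    "study_bonferroni",
    "covariate_association_scan",
    "herit_gwas_overlap_test",
    "ols_sex_scan",
    "overlap_hypergeom",
]


@dataclass
class GwasResult:
    """Per-SNP association table for one trait."""

    trait: str
    season: str
    n_individuals: int
    table: pd.DataFrame  # index snp id; columns chrom, pos, maf, beta, se, p, q
    lam_null: float = float("nan")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def bonferroni_threshold(self, alpha: float = 0.05) -> float:
        return alpha / self.n_snps

    def n_significant(self, q_cutoff: float | None = None, alpha: float = 0.05) -> int:
        if q_cutoff is None:
            return int((self.table["p"] <= self.bonferroni_threshold(alpha)).sum())
        return int((self.table["q"] <= q_cutoff).sum())

    def has_hit(self, q_cutoff: float = 0.2, alpha: float = 0.05) -> bool:
        """Any SNP at within-GWAS Bonferroni or at the q cutoff."""
        return self.n_significant(None, alpha) > 0 or self.n_significant(q_cutoff) > 0

    def lambda_gc(self) -> float:
        return genomic_control_lambda(self.table["p"].to_numpy())


def build_covariate_design(
    cov: CovariateTable, individuals, exclude: tuple[str, ...] = ()
) -> np.ndarray:
    """Intercept + age + sex(F=0, M=1) + one-hot collection group (drop first).

    ``exclude`` drops named covariates (e.g. the one being tested).
    """
    sub = cov.subset(individuals)
    cols = [np.ones(len(sub.data))]
    if "age" not in exclude:
        cols.append(sub.data["age"].to_numpy(dtype=float))
    if "sex" not in exclude:
        cols.append(sub.sex_numeric().to_numpy())
    if "collection_group" not in exclude:
        groups = sorted(set(sub.data["collection_group"]))
        for grp in groups[1:]:
            cols.append((sub.data["collection_group"] == grp).to_numpy(dtype=float))
    return np.column_stack(cols)


def residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of y on a full-rank design with intercept."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the first column whose removal restores full rank
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                raise ValueError(f"rank-deficient design: column {j} is collinear")
        raise ValueError("rank-deficient design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def run_gwas(
    trait_residuals: np.ndarray | pd.Series,
    g: GenotypeMatrix,
    K: KinshipMatrix,
    trait: str = "trait",
    season: str = "combined",
    maf_min: float = 0.10,
    mode: str = "exact",
    min_individuals: int = 30,
    K_eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> GwasResult:
    """Mixed-model GWAS of one residualized trait.

    Applies the analysis-subset MAF filter, scans every SNP with the LRT
    (intercept-only fixed design), and attaches within-GWAS q-values.
    """
    if isinstance(trait_residuals, pd.Series):
        individuals = list(trait_residuals.index)
        y = trait_residuals.to_numpy(dtype=float)
    else:
        individuals = g.individuals
        y = np.asarray(trait_residuals, dtype=float)
    if len(individuals) < min_individuals:
        raise ValueError(
            f"only {len(individuals)} individuals; below the power guard of {min_individuals}"
        )
    if np.ptp(y) == 0:
        raise ValueError("constant trait")
    sub = analysis_maf_filter(g, individuals, maf_min=maf_min)
    if K_eig is None:
        K_eig = eigendecompose_kinship(K.align(individuals))
    X = sub.values()
    # mean-impute residual missing dosages for the scan
    if np.isnan(X).any():
        mu = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), mu[None, :], X)
    res = scan_snps(y, X, K_eig, mode=mode)
    q, _ = qvalues(res["p"])
    table = pd.DataFrame(
        {
            "chrom": sub.snp_meta["chrom"].to_numpy(),
            "pos": sub.snp_meta["pos"].to_numpy(),
            "maf": sub.maf().to_numpy(),
            "beta": res["beta"],
            "se": res["se"],
            "p": res["p"],
            "q": q,
        },
        index=pd.Index(sub.snp_ids, name="snp"),
    )
    return GwasResult(
        trait=trait,
        season=season,
        n_individuals=len(individuals),
        table=table,
        lam_null=float(res["lam_null"]),
    )


def qvalues(p: np.ndarray, pi0: float | None = None) -> tuple[np.ndarray, float]:
    """Storey q-values with the smoother pi0 estimate.

    For fewer than 100 p-values the smoother is unstable, so pi0 falls back
    to 1 and the result coincides with Benjamini-Hochberg. Output is
    monotone non-decreasing in p and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 100:
            pi0 = 1.0
        else:
            lam = np.arange(0.05, 0.96, 0.05)
            pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
            spline = interpolate.UnivariateSpline(lam, pi0_lam, k=3)
            pi0 = float(np.clip(spline(lam[-1]), 1.0 / m, 1.0))
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, float(pi0)


def study_bonferroni(alpha: float, tests_per_gwas: list[tuple[int, int]]) -> float:
    """Study-wise Bonferroni threshold: alpha / total trait x SNP tests."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if not tests_per_gwas:
        raise ValueError("no GWAS listed")
    total = 0
    for n_traits, n_snps in tests_per_gwas:
        if n_traits <= 0 or n_snps <= 0:
            raise ValueError("trait and SNP counts must be positive")
        total += n_traits * n_snps
    return alpha / total


def covariate_association_scan(
    matrix: pd.DataFrame,
    predictor: str,
    cov: CovariateTable,
    K: KinshipMatrix,
) -> pd.DataFrame:
    """Mixed-model association of every taxon with age or sex.

    For each taxon, the *other* covariates are regressed out by OLS, then
    the predictor is tested with the kinship-aware LRT. q-values are
    computed across taxa. Returns a per-taxon (beta, p, q) table.
    """
    if predictor not in ("age", "sex"):
        raise ValueError("predictor must be 'age' or 'sex'")
    individuals = list(matrix.index)
    sub = cov.subset(individuals)
    if predictor == "sex":
        x = sub.sex_numeric().to_numpy()
        if np.ptp(x) == 0:
            raise ValueError("single-sex sample: sex scan impossible")
    else:
        x = sub.data["age"].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError("constant age")
    W = build_covariate_design(cov, individuals, exclude=(predictor,))
    Kal = K.align(individuals)
    eig = eigendecompose_kinship(Kal)
    rows = []
    for taxon in matrix.columns:
        y = residualize(matrix[taxon].to_numpy(dtype=float), W)
        beta, se, p = lrt_predictor(y, x, np.ones((len(individuals), 1)), eig)
        rows.append({"taxon": taxon, "beta": beta, "se": se, "p": p})
    out = pd.DataFrame(rows).set_index("taxon")
    out["q"], _ = qvalues(out["p"].to_numpy())
    return out


def herit_gwas_overlap_test(
    nonzero_flags,
    hit_flags,
    n_perm: int = 10_000,
    seed: int = 0,
    plus_one: bool = False,
) -> tuple[int, float]:
    """Permutation test for heritability-GWAS overlap across taxa.

    The observed statistic is the number of taxa flagged both heritable and
    carrying a genome-wide hit; the null permutes the heritability flags
    over taxa. Empirical p = #(perm overlap >= observed) / n_perm (can be
    exactly 0); ``plus_one`` applies the (count+1)/(n_perm+1) correction.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    h = np.asarray(nonzero_flags, dtype=bool)
    g = np.asarray(hit_flags, dtype=bool)
    if h.shape != g.shape:
        raise ValueError("flag vectors must have equal length")
    observed = int(np.sum(h & g))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += int(np.sum(rng.permutation(h) & g) >= observed)
    if plus_one:
        return observed, (count + 1) / (n_perm + 1)
    return observed, count / n_perm


def ols_sex_scan(matrix: pd.DataFrame, sex) -> pd.DataFrame:
    """Plain linear-model sex test per taxon (no kinship correction).

    Used for cross-population comparison where relatedness is unknown.
    Returns per-taxon (beta, p, q) with sex coded F=0, M=1.
    """
    sexv = pd.Series(sex)
    if set(sexv.astype(str)) <= {"F", "M"}:
        x = (sexv.astype(str) == "M").to_numpy(dtype=float)
    else:
        x = sexv.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("single-sex sample")
    n = x.size
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    rows = []
    for taxon in matrix.columns:
        y = matrix[taxon].to_numpy(dtype=float)
        beta = float(np.sum(xc * y) / sxx)
        resid = y - y.mean() - beta * xc
        s2 = float(np.sum(resid**2) / (n - 2))
        se = np.sqrt(s2 / sxx)
        t = beta / se if se > 0 else 0.0
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        rows.append({"taxon": taxon, "beta": beta, "se": se, "p": p})
    out = pd.DataFrame(rows).set_index("taxon")
    out["q"], _ = qvalues(out["p"].to_numpy())
    return out


def overlap_hypergeom(set_a, set_b, universe) -> float:
    """Upper-tail hypergeometric p for the overlap of two taxon sets."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    if set(set_a) - universe or set(set_b) - universe:
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))
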
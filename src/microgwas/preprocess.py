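"""Taxon-table preprocessing: subsampling, replicate combining, prevalence
filtering, inverse-normal transformation, correlated-taxon pruning, season
averaging, alpha diversity and PCA-vs-label QC.

The canonical per-season order is fixed:

    subsample -> combine replicates -> relative abundance -> prevalence
    filter -> inverse-normal transform -> correlation prune

For the combined-season analysis, taxa are first restricted to those passing
prevalence in *both* seasons, each season is transformed separately, values
are averaged for dual-season individuals, and pruning runs on the averaged
matrix. :func:`preprocess_season` and :func:`preprocess_combined` wire these
stages in that order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import LEVEL_RANK, TaxaCountTable

__all__ = [
    "NormalizedTaxaMatrix",
    "subsample_counts",
    "combine_replicates",
    "relative_abundance",
    "prevalence_filter",
    "inverse_normal_transform",
    "correlation_prune",
    "combine_seasons",
    "alpha_diversity",
    "pca_label_qc",
    "preprocess_season",
    "preprocess_combined",
]


@dataclass
class NormalizedTaxaMatrix:
    """Individuals x taxa matrix of inverse-normal-transformed abundances."""

    values: pd.DataFrame
    season: str = "combined"
    taxonomy: pd.DataFrame | None = None

    @property
    def individuals(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.values.columns)


def subsample_counts(table: TaxaCountTable, max_depth: int, seed: int = 0) -> TaxaCountTable:
    """Downsample each technical replicate to at most ``max_depth`` reads.

    Replicates above the depth are subsampled without replacement
    (multivariate hypergeometric), so expected taxon proportions are
    preserved; replicates at or below the depth pass through unchanged.
    """
    if max_depth <= 0:
        raise ValueError("max_depth must be positive")
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy(copy=True)
    totals = counts.sum(axis=1)
    for i in np.nonzero(totals > max_depth)[0]:
        counts[i] = rng.multivariate_hypergeometric(counts[i], max_depth)
    return TaxaCountTable(
        pd.DataFrame(counts, index=table.counts.index, columns=table.counts.columns),
        table.taxonomy,
    )


def combine_replicates(table: TaxaCountTable) -> TaxaCountTable:
    """Sum technical replicates within each individual-season."""
    combined = table.counts.groupby(level=["individual", "season"], sort=False).sum()
    combined.index = pd.MultiIndex.from_tuples(
        [(i, s, "combined") for i, s in combined.index],
        names=["individual", "season", "replicate"],
    )
    return TaxaCountTable(combined, table.taxonomy)


def relative_abundance(table: TaxaCountTable) -> pd.DataFrame:
    """Proportions per row; rows with zero total reads are dropped with a warning."""
    totals = table.counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} sample(s) with zero total reads", stacklevel=2
        )
    counts = table.counts.loc[~zero]
    return counts.div(counts.sum(axis=1), axis=0)


def prevalence_filter(
    table: TaxaCountTable, min_fraction: float = 0.75
) -> TaxaCountTable:
    """Keep taxa with >=1 read in at least ``min_fraction`` of individuals (inclusive)."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    per_indiv = table.counts.groupby(level="individual", sort=False).sum()
    prevalence = (per_indiv > 0).mean(axis=0)
    keep = prevalence[prevalence >= min_fraction].index
    if len(keep) == 0:
        warnings.warn("prevalence filter removed every taxon", stacklevel=2)
    return TaxaCountTable(table.counts[list(keep)], table.taxonomy.loc[list(keep)])


def inverse_normal_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse normal transform onto standard normal quantiles.

    Maps value of rank r (average ranks for ties) to
    ``Phi^-1((r - a) / (n + 1 - 2a))`` with the plotting-position offset
    a = 3/8 for n <= 10 and a = 1/2 otherwise — the convention of R's
    ``qqnorm``/``ppoints``. Monotone in the input by construction.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("inverse normal transform needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant input: taxon should have been dropped upstream")
    a = 3.0 / 8.0 if n <= 10 else 0.5
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - a) / (n + 1.0 - 2.0 * a))


def _int_matrix(rel: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for taxon in rel.columns:
        out[taxon] = inverse_normal_transform(rel[taxon].to_numpy())
    return pd.DataFrame(out, index=rel.index)


@dataclass
class PruneRecord:
    kept: str
    removed: str
    r: float
    reason: str  # "cross-level" or "same-level"


def correlation_prune(
    matrix: pd.DataFrame,
    taxonomy: pd.DataFrame,
    r_threshold: float = 0.9,
) -> tuple[pd.DataFrame, list[PruneRecord]]:
    """Remove redundant taxa until no pair has Pearson r >= threshold.

    Removal rules: for a pair at different taxonomic levels the broader
    (higher) level is removed, keeping the finer taxon; for a same-level
    pair the alphabetically first name is removed. Violating pairs are
    processed by descending |r| (ties broken lexicographically) and the
    remaining pairs re-checked after each removal, making the result
    deterministic.
    """
    cols = list(matrix.columns)
    missing = set(cols) - set(taxonomy.index)
    if missing:
        raise ValueError(f"taxonomy missing for taxa: {sorted(missing)[:5]}")
    corr = matrix.corr().to_numpy()
    alive = {t: i for i, t in enumerate(cols)}
    report: list[PruneRecord] = []

    def violating_pairs() -> list[tuple[float, str, str]]:
        names = sorted(alive)
        out = []
        for ai in range(len(names)):
            for bi in range(ai + 1, len(names)):
                a, b = names[ai], names[bi]
                r = corr[alive[a], alive[b]]
                if r >= r_threshold:
                    out.append((r, a, b))
        out.sort(key=lambda t: (-t[0], t[1], t[2]))
        return out

    while True:
        pairs = violating_pairs()
        if not pairs:
            break
        r, a, b = pairs[0]
        rank_a = LEVEL_RANK[taxonomy.loc[a, "level"]]
        rank_b = LEVEL_RANK[taxonomy.loc[b, "level"]]
        if rank_a != rank_b:
            # smaller rank = broader level; the broader taxon is removed
            removed = a if rank_a < rank_b else b
            reason = "cross-level"
        else:
            removed = min(a, b)
            reason = "same-level"
        kept = b if removed == a else a
        report.append(PruneRecord(kept=kept, removed=removed, r=float(r), reason=reason))
        del alive[removed]

    kept_cols = [t for t in cols if t in alive]
    return matrix[kept_cols], report


def combine_seasons(
    winter: NormalizedTaxaMatrix, summer: NormalizedTaxaMatrix
) -> NormalizedTaxaMatrix:
    """Average normalized values for dual-season individuals; union otherwise.

    Both inputs must already be restricted to taxa passing prevalence in
    both seasons and transformed within season.
    """
    common = [t for t in winter.taxa if t in set(summer.taxa)]
    if not common:
        raise ValueError("no taxa common to both seasons")
    w, s = winter.values[common], summer.values[common]
    both = w.index.intersection(s.index)
    only_w = w.index.difference(s.index)
    only_s = s.index.difference(w.index)
    avg = (w.loc[both] + s.loc[both]) / 2.0
    out = pd.concat([avg, w.loc[only_w], s.loc[only_s]]).sort_index()
    return NormalizedTaxaMatrix(out, season="combined", taxonomy=winter.taxonomy)


def alpha_diversity(genus_counts: np.ndarray | pd.Series) -> tuple[int, float, float]:
    """Richness S, Shannon H (natural log) and Pielou evenness J = H / ln S.

    Computed from raw genus-level counts, without normalization. J is NaN
    for S = 1 (evenness undefined for a single genus).
    """
    x = np.asarray(genus_counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero sample: diversity undefined")
    p = x[x > 0] / total
    S = int(p.size)
    H = float(-(p * np.log(p)).sum())
    J = H / np.log(S) if S > 1 else float("nan")
    return S, H, J


def pca_label_qc(
    matrix: pd.DataFrame | NormalizedTaxaMatrix,
    label: np.ndarray | pd.Series,
    k: int = 10,
) -> pd.DataFrame:
    """Correlate the top-k principal components with a per-individual label.

    Returns a DataFrame with per-PC Pearson r and p (point-biserial when
    the label is binary). Used to confirm e.g. that season is not captured
    by any leading PC of the combined matrix.
    """
    X = matrix.values if isinstance(matrix, NormalizedTaxaMatrix) else matrix
    lab = np.asarray(pd.Series(label).reindex(X.index) if isinstance(label, pd.Series) else label, dtype=float)
    if np.ptp(lab) == 0:
        raise ValueError("constant label")
    A = X.to_numpy(dtype=float)
    n = A.shape[0]
    if n <= k:
        raise ValueError("need more individuals than components")
    A = A - A.mean(axis=0)
    U, sing, _ = np.linalg.svd(A, full_matrices=False)
    k = min(k, (sing > 1e-12).sum())
    scores = U[:, :k] * sing[:k]
    rows = []
    for j in range(k):
        r, p = stats.pearsonr(scores[:, j], lab)
        rows.append({"pc": j + 1, "var_explained": sing[j] ** 2 / (sing**2).sum(), "r": r, "p": p})
    return pd.DataFrame(rows).set_index("pc")


# ---------------------------------------------------------------------------
# wired pipelines


def preprocess_season(
    table: TaxaCountTable,
    season: str,
    max_depth: int = 2_000_000,
    min_prevalence: float = 0.75,
    prune_r: float = 0.9,
    seed: int = 0,
    taxa_whitelist: list[str] | None = None,
    prune: bool = True,
) -> tuple[NormalizedTaxaMatrix, list[PruneRecord]]:
    """Full single-season preprocessing in the canonical order."""
    tab = table.for_season(season)
    tab = subsample_counts(tab, max_depth, seed=seed)
    tab = combine_replicates(tab)
    if taxa_whitelist is not None:
        tab = TaxaCountTable(tab.counts[taxa_whitelist], tab.taxonomy.loc[taxa_whitelist])
    else:
        tab = prevalence_filter(tab, min_prevalence)
    rel = relative_abundance(tab)
    rel.index = rel.index.get_level_values("individual")
    normed = _int_matrix(rel)
    if prune:
        normed, report = correlation_prune(normed, tab.taxonomy, prune_r)
    else:
        report = []
    return (
        NormalizedTaxaMatrix(normed, season=season, taxonomy=tab.taxonomy.loc[list(normed.columns)]),
        report,
    )


def prevalent_taxa(
    table: TaxaCountTable, season: str, max_depth: int, min_prevalence: float, seed: int
) -> list[str]:
    tab = combine_replicates(subsample_counts(table.for_season(season), max_depth, seed=seed))
    return prevalence_filter(tab, min_prevalence).taxa


def preprocess_combined(
    table: TaxaCountTable,
    seasons: tuple[str, str],
    max_depth: int = 2_000_000,
    min_prevalence: float = 0.75,
    prune_r: float = 0.9,
    seed: int = 0,
) -> tuple[NormalizedTaxaMatrix, list[PruneRecord]]:
    """Combined-season preprocessing.

    Restricts to taxa prevalent in both seasons, transforms each season
    separately, averages dual-season individuals, then prunes correlated
    taxa on the averaged matrix.
    """
    s1, s2 = seasons
    common = [
        t
        for t in prevalent_taxa(table, s1, max_depth, min_prevalence, seed)
        if t in set(prevalent_taxa(table, s2, max_depth, min_prevalence, seed))
    ]
    m1, _ = preprocess_season(
        table, s1, max_depth, min_prevalence, prune_r, seed, taxa_whitelist=common, prune=False
    )
    m2, _ = preprocess_season(
        table, s2, max_depth, min_prevalence, prune_r, seed, taxa_whitelist=common, prune=False
    )
    combined = combine_seasons(m1, m2)
    pruned, report = correlation_prune(combined.values, table.taxonomy, prune_r)
    return (
        NormalizedTaxaMatrix(
            pruned, season="combined", taxonomy=table.taxonomy.loc[list(pruned.columns)]
        ),
        report,
    )
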
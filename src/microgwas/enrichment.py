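"""Candidate-tissue identification from open-chromatin enrichment.

Cell lines are clustered into tissues from binary DHS-peak presence
profiles (Euclidean distance, average-linkage hierarchical clustering); each
tissue's peak set is the base-pair intersection of its member cell lines'
peaks. For a GWAS, fold enrichment per tissue is the in-peak fraction among
SNPs at or below a p-value threshold divided by the in-peak fraction among
all tested SNPs, over a fixed ladder of thresholds, keeping only bins with
at least ``min_snps`` SNPs. Significance for the smallest retained bin is
calibrated by whole-GWAS permutation: trait values are shuffled across
individuals, the scan re-run, and the same number of top SNPs scored — so
the null preserves genotype and peak structure exactly.

Reported empirical p-values are not corrected for multiple testing across
tissues.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .intervals import PeakSet, intersect_peaks, union_peaks
from .lmm import null_lambda_rotated, scan_snps

__all__ = [
    "DEFAULT_THRESHOLDS",
    "TissueAssignment",
    "EnrichmentProfile",
    "cluster_cell_lines",
    "tissue_peaks",
    "snp_in_peak_mask",
    "enrichment_profile",
    "enrichment_permutation_test",
]

DEFAULT_THRESHOLDS = (
    1.0, 0.5, 0.1, 0.05, 0.01, 0.005, 0.001, 0.0005,
    0.0001, 0.00005, 0.00001, 0.000005,
)


@dataclass
class TissueAssignment:
    """Cell line -> tissue labels produced by clustering."""

    assignment: dict[str, str]
    k: int

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for line, tissue in self.assignment.items():
            out.setdefault(tissue, []).append(line)
        return out


@dataclass
class EnrichmentProfile:
    """Per-tissue fold enrichments over p-value threshold bins."""

    trait: str
    bins: pd.DataFrame  # columns: tissue, threshold, n_snps, fold
    smallest_bin_threshold: float
    n_top: int  # SNPs in the smallest retained bin (permutation match size)

    def fold(self, tissue: str, threshold: float) -> float:
        sel = self.bins[(self.bins["tissue"] == tissue) & (self.bins["threshold"] == threshold)]
        if sel.empty:
            raise KeyError(f"no retained bin for {tissue} at {threshold}")
        return float(sel["fold"].iloc[0])

    def smallest_bin_folds(self) -> pd.Series:
        sel = self.bins[self.bins["threshold"] == self.smallest_bin_threshold]
        return sel.set_index("tissue")["fold"]


def cluster_cell_lines(
    peaksets: Mapping[str, PeakSet] | Sequence[PeakSet], k: int = 16
) -> TissueAssignment:
    """Cluster cell lines into k tissues from binary peak-presence profiles.

    Features are the merged union of all peak intervals across lines; a
    line scores 1 on a feature it overlaps. Average-linkage hierarchical
    clustering on Euclidean distances, cut into k groups. Deterministic
    given input order; with an all-zero distance matrix the cut is an
    arbitrary but stable split by input order.
    """
    if not isinstance(peaksets, Mapping):
        peaksets = {ps.label or f"line{i}": ps for i, ps in enumerate(peaksets)}
    labels = list(peaksets)
    if k > len(labels):
        raise ValueError(f"k={k} exceeds number of cell lines ({len(labels)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    features = union_peaks(peaksets.values())
    feat_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(features):
        feat_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    profiles = np.zeros((len(labels), len(features)), dtype=float)
    for i, lab in enumerate(labels):
        table = peaksets[lab].by_chrom()
        for c, feats in feat_by_chrom.items():
            rows = table.get(c)
            if rows is None:
                continue
            starts, ends = rows[:, 0], rows[:, 1]
            fs = np.array([f[0] for f in feats])
            fe = np.array([f[1] for f in feats])
            fj = np.array([f[2] for f in feats])
            # line intervals are disjoint & sorted: only the rightmost one
            # starting before the feature's end can overlap it
            idx = np.searchsorted(starts, fe, side="left") - 1
            ok = idx >= 0
            ok[ok] = ends[idx[ok]] > fs[ok]
            profiles[i, fj[ok]] = 1.0
    if len(labels) == 1:
        return TissueAssignment({labels[0]: "tissue_1"}, 1)
    dist = pdist(profiles, metric="euclidean")
    if np.all(dist == 0):
        # degenerate: identical lines; split stably by input order
        groups = np.array_split(np.arange(len(labels)), k)
        assignment = {}
        for gi, grp in enumerate(groups):
            for i in grp:
                assignment[labels[i]] = f"tissue_{gi + 1}"
        return TissueAssignment(assignment, k)
    Z = linkage(dist, method="average")
    flat = fcluster(Z, t=k, criterion="maxclust")
    assignment = {lab: f"tissue_{c}" for lab, c in zip(labels, flat)}
    return TissueAssignment(assignment, k)


def tissue_peaks(
    assignment: TissueAssignment, peaksets: Mapping[str, PeakSet]
) -> dict[str, PeakSet]:
    """Per-tissue peak set: iterated intersection over member cell lines."""
    out: dict[str, PeakSet] = {}
    for tissue, members in assignment.members().items():
        missing = [m for m in members if m not in peaksets]
        if missing:
            raise KeyError(f"no peak set for cell line(s) {missing[:3]}")
        if not members:
            raise ValueError(f"tissue {tissue} has no member cell lines")
        out[tissue] = reduce(
            lambda a, b: intersect_peaks(a, b, label=tissue),
            (peaksets[m] for m in members),
        )
        out[tissue].label = tissue
    return out


def snp_in_peak_mask(
    snp_chroms: Sequence[str],
    snp_positions: Sequence[int],
    tissue_peak_map: Mapping[str, PeakSet],
) -> pd.DataFrame:
    """Boolean SNP x tissue membership matrix (0-based positions, s <= p < e).

    SNPs on chromosomes absent from a tissue's peaks are simply False.
    Computed once and reused across traits and permutations.
    """
    cols = {}
    for tissue, peaks in tissue_peak_map.items():
        cols[tissue] = peaks.contains_positions(snp_chroms, snp_positions)
    return pd.DataFrame(cols)


def enrichment_profile(
    pvals: np.ndarray,
    mask: pd.DataFrame,
    trait: str = "trait",
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    min_snps: int = 50,
) -> EnrichmentProfile:
    """Fold enrichment per tissue over the p-value threshold ladder.

    fold(tissue, t) = (in-peak fraction among SNPs with p <= t)
                      / (in-peak fraction among all tested SNPs).
    Bins with fewer than ``min_snps`` SNPs are omitted. Tissues whose
    genome-wide in-peak fraction is zero are skipped (fold undefined).
    """
    p = np.asarray(pvals, dtype=float)
    if len(mask) != p.size:
        raise ValueError("mask not aligned with p-values")
    genome_frac = mask.mean(axis=0)
    rows = []
    retained = []
    for t in sorted(thresholds, reverse=True):
        in_bin = p <= t
        n_bin = int(in_bin.sum())
        if n_bin < min_snps:
            continue
        retained.append((t, n_bin))
        for tissue in mask.columns:
            gf = genome_frac[tissue]
            if gf == 0:
                import warnings

                warnings.warn(f"tissue {tissue} has no SNPs in peaks; skipped", stacklevel=2)
                continue
            fold = mask[tissue].to_numpy()[in_bin].mean() / gf
            rows.append(
                {"tissue": tissue, "threshold": t, "n_snps": n_bin, "fold": float(fold)}
            )
    if not retained:
        raise ValueError("no threshold bin holds the minimum number of SNPs")
    smallest_t, n_top = retained[-1]
    return EnrichmentProfile(
        trait=trait,
        bins=pd.DataFrame(rows),
        smallest_bin_threshold=smallest_t,
        n_top=n_top,
    )


def _top_folds(p: np.ndarray, n_top: int, mask_values: np.ndarray, genome_frac: np.ndarray) -> np.ndarray:
    top = np.argpartition(p, n_top - 1)[:n_top]
    return mask_values[top].mean(axis=0) / genome_frac


def _batched_perm_lrt(Y: np.ndarray, Xrot: np.ndarray, X2rot: np.ndarray,
                      c: np.ndarray, d: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Fixed-lambda LRT statistics for a batch of (already rotated) traits.

    ``Y`` is (n, B) rotated permuted traits, ``lams`` the per-trait null
    lambdas. Because lambda is shared across SNPs within a trait, the sum of
    log-variances cancels in the LRT and each test reduces to a weighted
    simple regression, so the whole batch is three GEMMs. Returns (p, B)
    LRT statistics.
    """
    n = Y.shape[0]
    W = 1.0 / (d[:, None] * lams[None, :] + 1.0)  # (n, B)
    scc = (c * c) @ W
    scy = np.einsum("n,nb,nb->b", c, Y, W)
    syy = np.einsum("nb,nb->b", Y * Y, W)
    SCX = Xrot.T @ (c[:, None] * W)
    SXY = Xrot.T @ (Y * W)
    SXX = X2rot.T @ W
    sxx_c = SXX - SCX**2 / scc[None, :]
    sxy_c = SXY - SCX * scy[None, :] / scc[None, :]
    syy_c = syy - scy**2 / scc
    with np.errstate(divide="ignore", invalid="ignore"):
        rss1 = np.maximum(syy_c[None, :] - np.where(sxx_c > 0, sxy_c**2 / np.where(sxx_c > 0, sxx_c, 1.0), 0.0), 1e-300)
    return n * np.log(syy_c[None, :] / rss1)


def enrichment_permutation_test(
    trait_residuals: np.ndarray,
    snps: np.ndarray,
    K_eig: tuple[np.ndarray, np.ndarray],
    mask: pd.DataFrame,
    n_perm: int = 1000,
    n_top: int | None = None,
    seed: int = 0,
    mode: str = "fast",
    actual_pvals: np.ndarray | None = None,
    plus_one: bool = False,
) -> pd.DataFrame:
    """GWAS-permutation null for the smallest-bin tissue enrichments.

    Shuffles the trait across individuals ``n_perm`` times, re-runs the
    whole scan (fast mode refits the null lambda per permutation and reuses
    it across SNPs), takes the ``n_top`` smallest-p SNPs and computes each
    tissue's fold. Empirical p = #(perm fold >= actual fold) / n_perm.
    Returns a per-tissue table with actual fold, empirical p and the null
    mean; the full null distributions are attached as ``.attrs['null']``.
    """
    y = np.asarray(trait_residuals, dtype=float)
    p_count = snps.shape[1]
    if n_top is None:
        raise ValueError("n_top must be given (size of the actual smallest bin)")
    if n_top > p_count:
        raise ValueError("n_top exceeds the number of SNPs")
    if actual_pvals is None:
        actual_pvals = scan_snps(y, snps, K_eig, mode=mode)["p"]
    mask_values = mask.to_numpy(dtype=float)
    genome_frac = mask_values.mean(axis=0)
    if (genome_frac == 0).any():
        keep = genome_frac > 0
        mask_values = mask_values[:, keep]
        genome_frac = genome_frac[keep]
        tissues = [t for t, k in zip(mask.columns, keep) if k]
    else:
        tissues = list(mask.columns)
    actual = _top_folds(np.asarray(actual_pvals, dtype=float), n_top, mask_values, genome_frac)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(tissues)))
    if mode == "fast":
        d, U = K_eig
        Xrot = U.T @ np.asarray(snps, dtype=float)
        X2rot = Xrot * Xrot
        c = U.T @ np.ones(y.size)
        chunk = 100
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            Yp = np.column_stack([rng.permutation(y) for _ in range(b)])
            Yrot = U.T @ Yp
            lams = np.array(
                [null_lambda_rotated(Yrot[:, i], c, d) for i in range(b)]
            )
            lrt = _batched_perm_lrt(Yrot, Xrot, X2rot, c, d, lams)
            # LRT is monotone decreasing in p, so rank by -LRT directly
            for i in range(b):
                top = np.argpartition(-lrt[:, i], n_top - 1)[:n_top]
                null[done + i] = mask_values[top].mean(axis=0) / genome_frac
            done += b
    else:
        for b in range(n_perm):
            yp = rng.permutation(y)
            pv = scan_snps(yp, snps, K_eig, mode=mode)["p"]
            null[b] = _top_folds(pv, n_top, mask_values, genome_frac)
    count = (null >= actual[None, :]).sum(axis=0)
    if plus_one:
        emp_p = (count + 1) / (n_perm + 1)
    else:
        emp_p = count / n_perm
    out = pd.DataFrame(
        {"fold": actual, "empirical_p": emp_p, "null_mean": null.mean(axis=0)},
        index=pd.Index(tissues, name="tissue"),
    )
    out.attrs["null"] = pd.DataFrame(null, columns=tissues)
    return out
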
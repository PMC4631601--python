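"""Genotype quality control and genomic relatedness.

QC mirrors standard array-genotyping practice: SNPs are retained when minor
allele frequency >= 5%, call rate >= 95% and the Hardy-Weinberg exact-test
p-value >= 0.001 (all thresholds inclusive). A second, stricter MAF >= 10%
filter is recomputed on each analysis subset of individuals before
association testing ("lower than 10%" removed, i.e. strictly-below).

Relatedness is the centered genomic relationship matrix (GRM)
``K = (1/p) sum_s (g_s - 2 f_s)(g_s - 2 f_s)^T``; a pedigree-based IBD
matrix would need the actual pedigree, and the GRM plays the identical role
as the random-effect covariance of the mixed model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, KinshipMatrix

__all__ = [
    "hwe_exact_test",
    "snp_qc",
    "analysis_maf_filter",
    "kinship_matrix",
    "QcReport",
]


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability is less than or
    equal to that of the observed one (the standard exact HWE construction).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotyped individuals")
    n_a = 2 * n_aa + n_Aa  # minor-allele count (labelling is symmetric)
    # heterozygote counts compatible with the allele totals share parity
    h_min = n_a % 2
    h_max = min(n_a, 2 * n - n_a)
    hs = np.arange(h_min, h_max + 1, 2)
    # log P(h | allele counts) up to a shared constant:
    # P(h) ∝ n! / (hom1! hom2! h!) * 2^h  with hom1=(n_a-h)/2, hom2=n-(n_a+h)/2
    logp = np.array(
        [
            h * math.log(2.0)
            - math.lgamma((n_a - h) / 2 + 1)
            - math.lgamma(n - (n_a + h) / 2 + 1)
            - math.lgamma(h + 1)
            for h in hs
        ]
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = probs[np.nonzero(hs == n_Aa)[0][0]]
    # two-sided: sum of all outcomes no more probable than the observed
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


@dataclass
class QcReport:
    n_input: int
    n_kept: int
    fail_maf: int
    fail_call_rate: int
    fail_hwe: int
    notes: str = (
        "Mendelian-error filtering not applied (requires pedigree data, unavailable)."
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["n_input", "n_kept", "fail_maf", "fail_call_rate", "fail_hwe"],
                "value": [self.n_input, self.n_kept, self.fail_maf, self.fail_call_rate, self.fail_hwe],
            }
        )


def snp_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 0.001,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs failing MAF / call-rate / HWE (inclusive thresholds pass)."""
    for name, v in [("maf_min", maf_min), ("call_rate_min", call_rate_min), ("hwe_p_min", hwe_p_min)]:
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    maf = g.maf().to_numpy()
    call = g.call_rate().to_numpy()
    dos = g.values()
    hwe_p = np.ones(g.n_snps)
    for j in range(g.n_snps):
        col = dos[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            hwe_p[j] = 1.0
            continue
        hwe_p[j] = hwe_exact_test(
            int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2))
        )
    pass_maf = maf >= maf_min
    pass_call = call >= call_rate_min
    pass_hwe = hwe_p >= hwe_p_min
    keep = pass_maf & pass_call & pass_hwe
    report = QcReport(
        n_input=g.n_snps,
        n_kept=int(keep.sum()),
        fail_maf=int((~pass_maf).sum()),
        fail_call_rate=int((~pass_call).sum()),
        fail_hwe=int((~pass_hwe).sum()),
    )
    kept_ids = [s for s, k in zip(g.snp_ids, keep) if k]
    return g.subset_snps(kept_ids), report


def analysis_maf_filter(
    g: GenotypeMatrix, individuals_in_analysis, maf_min: float = 0.10
) -> GenotypeMatrix:
    """Re-filter on the analysis subset: MAF strictly below ``maf_min`` removed."""
    ids = list(individuals_in_analysis)
    if not ids:
        raise ValueError("empty analysis subset")
    sub = g.subset_individuals(ids)
    maf = sub.maf().to_numpy()
    keep = [s for s, m in zip(sub.snp_ids, maf) if m >= maf_min]
    return sub.subset_snps(keep)


def kinship_matrix(g: GenotypeMatrix, method: str = "centered") -> KinshipMatrix:
    """Genomic relationship matrix from post-QC dosages.

    Missing dosages are mean-imputed per SNP. ``centered`` (default):
    ``K = Z Z^T / p`` with ``Z = g - 2f``; ``standardized`` additionally
    divides each SNP by ``sqrt(2 f (1-f))``. Monomorphic SNPs carry no
    relatedness information and are skipped with a warning.
    """
    if method not in ("centered", "standardized"):
        raise ValueError(f"unknown kinship method {method!r}")
    X = g.values()
    f = np.nanmean(X, axis=0) / 2.0
    # mean imputation
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X = np.where(nan_mask, (2.0 * f)[None, :], X)
    poly = (f > 0) & (f < 1)
    if not poly.all():
        warnings.warn(
            f"skipping {int((~poly).sum())} monomorphic SNP(s) in kinship", stacklevel=2
        )
    X, f = X[:, poly], f[poly]
    Z = X - 2.0 * f[None, :]
    if method == "standardized":
        Z = Z / np.sqrt(2.0 * f * (1.0 - f))[None, :]
    K = Z @ Z.T / Z.shape[1]
    return KinshipMatrix(K, g.individuals)
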
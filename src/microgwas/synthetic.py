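"""Synthetic founder-population data with known ground truth.

Every downstream stage of the pipeline (preprocessing, kinship, mixed-model
association, heritability, tissue enrichment) is exercised on data from this
module, which emulates the structure of a communal founder population sampled
in two seasons with technical replicates:

* family-structured genotypes — non-overlapping sibships drawn from two
  simulated parents each, giving a block "true" kinship of ~0.5 within
  families and 0 between (1 on the diagonal, genomic-relationship scale);
* taxon read counts from a latent-trait model — per-taxon latent abundance
  z = planted SNP effects + polygenic term with variance h2 + sex/age/
  collection-group effects + noise, pushed through a softmax over taxa and
  sampled as multinomial reads per technical replicate (compositional
  counts);
* DNase-hypersensitivity peak sets per cell line in which causal variants
  for chosen taxa sit inside peaks shared by every cell line of one "true"
  tissue.

SNPs are independent given the pedigree: there is no linkage disequilibrium
beyond family sharing (a deliberate simplification — see the methods note).

All randomness flows from a single root seed; each generator derives its own
child stream by a fixed offset, so outputs are reproducible individually and
jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import Interval, PeakSet
from .io import CovariateTable, GenotypeMatrix, KinshipMatrix, TaxaCountTable

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_taxa_counts",
    "simulate_dhs_peaks",
]

# fixed offsets for per-generator child RNG streams
_STREAM_GENO = 1
_STREAM_COVAR = 2
_STREAM_TAXA = 3
_STREAM_PEAKS = 4


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults emulate a desk-scale version of a founder-population microbiome
    study: ~200 related individuals in sibships, biallelic SNPs with a
    uniform MAF spectrum, ~2 seasons x 2 technical replicates, and a handful
    of planted genetic and covariate effects (all in latent-trait SD units,
    i.e. relative to unit residual noise).
    """

    n_individuals: int = 200
    n_snps: int = 2000
    n_families: int = 40
    family_size: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_taxa: int = 40
    planted_effects: list[tuple[str, str, float]] = field(default_factory=list)
    taxon_h2: dict[str, float] = field(default_factory=dict)
    sex_effects: dict[str, float] = field(default_factory=dict)
    age_effects: dict[str, float] = field(default_factory=dict)
    seasons: int = 2
    replicates_per_season: int = 2
    reads_per_replicate: int = 100_000
    genome_length: int = 5_000_000
    n_cell_lines: int = 20
    n_tissues: int = 5
    causal_tissue: int = 0
    n_collection_groups: int = 5
    collection_effect_sd: float = 0.25
    season_effect_sd: float = 0.5
    monozygotic: bool = False
    peaks_per_tissue: int = 1500
    peak_width: int = 300
    within_tissue_share: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_individuals": self.n_individuals,
            "n_snps": self.n_snps,
            "n_families": self.n_families,
            "family_size": self.family_size,
            "n_taxa": self.n_taxa,
            "seasons": self.seasons,
            "replicates_per_season": self.replicates_per_season,
            "reads_per_replicate": self.reads_per_replicate,
            "genome_length": self.genome_length,
            "n_cell_lines": self.n_cell_lines,
            "n_tissues": self.n_tissues,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"config error: {name} must be positive, got {v}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"config error: maf_range must lie within (0, 0.5], got {self.maf_range}")
        for taxon, h2 in self.taxon_h2.items():
            if not (0 <= h2 < 1):
                raise ValueError(f"config error: heritability of {taxon} must be in [0,1), got {h2}")
        if self.n_families * self.family_size < self.n_individuals:
            raise ValueError(
                "config error: n_families * family_size must be >= n_individuals"
            )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def taxon_names(self) -> list[str]:
        return [f"g__taxon{j:03d}" for j in range(self.n_taxa)]

    def snp_names(self) -> list[str]:
        return [f"snp{j:05d}" for j in range(self.n_snps)]


@dataclass
class SimulationTruth:
    """Ground truth attached to a simulated cohort."""

    true_kinship: KinshipMatrix
    causal: dict[str, list[tuple[str, float]]]  # taxon -> [(snp, effect)]
    h2: dict[str, float]
    latent: pd.DataFrame  # individuals x taxa latent traits (no season shift)
    causal_positions: dict[str, int]  # snp -> 0-based position


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, KinshipMatrix]:
    """Sibship genotypes plus the pedigree ("true") kinship matrix.

    Each family has two simulated parents; every child draws one of each
    parent's two haplotypes independently per SNP, so full sibs share half
    their alleles in expectation. With ``monozygotic=True`` all sibs within
    a family are genetic copies of the first (kinship 1 within family).
    """
    rng = config.rng(_STREAM_GENO)
    n, p = config.n_individuals, config.n_snps
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=p)

    # distinct sorted positions on a single synthetic chromosome
    if config.genome_length < p:
        raise ValueError("config error: genome_length smaller than n_snps")
    positions = np.sort(rng.choice(config.genome_length, size=p, replace=False, shuffle=False))

    fam_of = np.repeat(np.arange(config.n_families), config.family_size)[:n]
    dosages = np.empty((n, p), dtype=np.int8)
    i = 0
    for fam in range(config.n_families):
        size = int(np.sum(fam_of == fam))
        if size == 0:
            continue
        hap = rng.random((4, p)) < freqs  # maternal x2, paternal x2
        pick_m = rng.integers(0, 2, size=(size, p))
        pick_p = rng.integers(0, 2, size=(size, p))
        cols = np.arange(p)[None, :]
        child = hap[pick_m, cols].astype(np.int8) + hap[2 + pick_p, cols].astype(np.int8)
        if config.monozygotic:
            child = np.repeat(child[:1], size, axis=0)
        dosages[i : i + size] = child
        i += size

    ids = [f"ind{k:04d}" for k in range(n)]
    snp_ids = config.snp_names()
    meta = pd.DataFrame(
        {"chrom": "chr1", "pos": positions}, index=pd.Index(snp_ids, name="snp")
    )
    g = GenotypeMatrix(
        pd.DataFrame(dosages.astype(float), index=pd.Index(ids, name="individual"), columns=snp_ids),
        meta,
    )

    within = 1.0 if config.monozygotic else 0.5
    K = np.where(fam_of[:, None] == fam_of[None, :], within, 0.0)
    np.fill_diagonal(K, 1.0)
    return g, KinshipMatrix(K, ids)


def simulate_covariates(config: SimulationConfig, individuals: Sequence[str]) -> CovariateTable:
    """Age (16-85 y), balanced sex, and a collection-date factor."""
    rng = config.rng(_STREAM_COVAR)
    n = len(individuals)
    age = rng.integers(16, 86, size=n).astype(float)
    sex = np.array(["F", "M"])[rng.integers(0, 2, size=n)]
    group = np.array([f"grp{k}" for k in rng.integers(0, config.n_collection_groups, size=n)])
    df = pd.DataFrame(
        {"age": age, "sex": sex, "collection_group": group},
        index=pd.Index(list(individuals), name="individual"),
    )
    return CovariateTable(df)


def simulate_taxa_counts(
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    config: SimulationConfig,
    true_kinship: KinshipMatrix | None = None,
) -> tuple[TaxaCountTable, SimulationTruth]:
    """Latent-trait taxon counts with planted genetic and covariate effects.

    Per taxon j the latent trait is
    ``z_j = sum_c beta_c (g_c - 2 f_c) + u_j + b_sex sex + b_age age_std + group shift + e_j``
    with ``u_j ~ N(0, h2_j K)`` and ``e_j ~ N(0, 1 - h2_j)``, so the
    covariate-free part has narrow-sense heritability h2_j in expectation and
    planted per-allele effects are in residual-SD units. Counts per technical
    replicate are multinomial over taxa with probabilities
    ``softmax(alpha_j + z_j + season shift)``, where alpha sets a realistic
    skewed abundance profile.
    """
    rng = config.rng(_STREAM_TAXA)
    indiv = genotypes.individuals
    missing = set(covariates.individuals) ^ set(indiv)
    if set(indiv) - set(covariates.individuals):
        raise ValueError(f"covariates missing for individuals: {sorted(missing)[:5]}")
    n = len(indiv)
    taxa = config.taxon_names()

    # cholesky of the true kinship for the polygenic draw
    if true_kinship is None:
        L = np.eye(n)
    else:
        K = true_kinship.align(indiv).values
        w, U = np.linalg.eigh(K)
        L = U * np.sqrt(np.clip(w, 0.0, None))

    cov = covariates.data.loc[indiv]
    sex01 = (cov["sex"].astype(str) == "M").to_numpy(dtype=float)
    age = cov["age"].to_numpy(dtype=float)
    age_std = (age - age.mean()) / age.std() if age.std() > 0 else np.zeros(n)
    groups = sorted(set(cov["collection_group"]))
    group_shift = {
        grp: s
        for grp, s in zip(groups, rng.normal(0.0, config.collection_effect_sd, len(groups)))
    }
    group_vec = cov["collection_group"].map(group_shift).to_numpy(dtype=float)

    planted: dict[str, list[tuple[str, float]]] = {}
    for taxon, snp, beta in config.planted_effects:
        if snp not in genotypes.dosages.columns:
            raise ValueError(f"planted snp {snp!r} absent from genotype matrix")
        if taxon not in taxa:
            raise ValueError(f"planted taxon {taxon!r} not among simulated taxa")
        planted.setdefault(taxon, []).append((snp, float(beta)))

    alpha = rng.normal(0.0, 2.0, size=config.n_taxa)  # skewed base abundances
    season_shift = rng.normal(
        0.0, config.season_effect_sd, size=(config.seasons, config.n_taxa)
    )

    z = np.zeros((n, config.n_taxa))
    h2_map = {t: float(config.taxon_h2.get(t, 0.0)) for t in taxa}
    for j, taxon in enumerate(taxa):
        h2 = h2_map[taxon]
        if h2 > 0:
            z[:, j] += np.sqrt(h2) * (L @ rng.standard_normal(n))
        z[:, j] += np.sqrt(1.0 - h2) * rng.standard_normal(n)
        for snp, beta in planted.get(taxon, []):
            gvec = genotypes.dosages[snp].to_numpy(dtype=float)
            z[:, j] += beta * (gvec - gvec.mean())
        z[:, j] += config.sex_effects.get(taxon, 0.0) * sex01
        z[:, j] += config.age_effects.get(taxon, 0.0) * age_std
        z[:, j] += group_vec

    season_names = [f"season{s}" for s in range(config.seasons)]
    rows, index = [], []
    for s in range(config.seasons):
        logit = alpha[None, :] + z + season_shift[s][None, :]
        prob = np.exp(logit - logit.max(axis=1, keepdims=True))
        prob /= prob.sum(axis=1, keepdims=True)
        for i in range(n):
            for r in range(config.replicates_per_season):
                rows.append(rng.multinomial(config.reads_per_replicate, prob[i]))
                index.append((indiv[i], season_names[s], f"rep{r}"))
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64),
        index=pd.MultiIndex.from_tuples(index, names=["individual", "season", "replicate"]),
        columns=taxa,
    )
    taxonomy = pd.DataFrame(
        {"level": "genus", "lineage": [f"p__phylumX;g__{t}" for t in taxa]},
        index=pd.Index(taxa, name="taxon"),
    )
    table = TaxaCountTable(counts, taxonomy)

    causal_positions = {
        snp: int(genotypes.snp_meta.loc[snp, "pos"])
        for lst in planted.values()
        for snp, _ in lst
    }
    truth = SimulationTruth(
        true_kinship=true_kinship
        if true_kinship is not None
        else KinshipMatrix(np.eye(n), list(indiv)),
        causal=planted,
        h2=h2_map,
        latent=pd.DataFrame(z, index=pd.Index(indiv, name="individual"), columns=taxa),
        causal_positions=causal_positions,
    )
    return table, truth


def simulate_dhs_peaks(
    config: SimulationConfig, causal_snps: Mapping[str, int] | Sequence[int]
) -> tuple[dict[str, PeakSet], pd.DataFrame]:
    """Per-cell-line DHS peak sets with one planted causal tissue.

    Each tissue has an archetypal peak set laid out on non-overlapping slots
    of the synthetic genome; its cell lines keep each archetype peak with
    probability ``within_tissue_share`` and add a matching number of private
    peaks, so lines of one tissue share most of their intervals. Every causal
    SNP position is covered by a "core" peak present in all cell lines of the
    causal tissue (and only guaranteed there).

    Returns the per-cell-line peak sets and a cell-line -> tissue truth table.
    """
    rng = config.rng(_STREAM_PEAKS)
    if isinstance(causal_snps, Mapping):
        causal_pos = sorted(int(p) for p in causal_snps.values())
    else:
        causal_pos = sorted(int(p) for p in causal_snps)
    width = config.peak_width
    slot = 2 * width
    n_slots = config.genome_length // slot
    if n_slots < config.peaks_per_tissue * 2:
        raise ValueError("config error: genome too small for requested peak density")
    for pos in causal_pos:
        if not (0 <= pos < config.genome_length):
            raise ValueError(f"causal SNP position {pos} outside genome of length {config.genome_length}")

    causal_slots = {pos // slot for pos in causal_pos}

    tissues = [f"tissue{t:02d}" for t in range(config.n_tissues)]
    causal_tissue = tissues[int(config.causal_tissue)]

    def slot_interval(k: int) -> Interval:
        start = k * slot + (slot - width) // 2
        return Interval("chr1", start, start + width)

    def core_intervals() -> list[Interval]:
        # peaks guaranteed to cover each causal SNP
        out = []
        for pos in causal_pos:
            start = max(0, pos - width // 2)
            out.append(Interval("chr1", start, min(config.genome_length, start + width)))
        return out

    line_of_tissue: dict[str, list[str]] = {t: [] for t in tissues}
    for i in range(config.n_cell_lines):
        t = tissues[i % config.n_tissues]
        line_of_tissue[t].append(f"{t}_line{len(line_of_tissue[t])}")

    free_slots = np.array(sorted(set(range(n_slots)) - causal_slots))
    peaksets: dict[str, PeakSet] = {}
    assignment_rows = []
    for t in tissues:
        arch_slots = rng.choice(free_slots, size=config.peaks_per_tissue, replace=False, shuffle=False)
        arch = [slot_interval(int(k)) for k in arch_slots]
        core = core_intervals() if t == causal_tissue else []
        spare = np.setdiff1d(free_slots, arch_slots)
        for line in line_of_tissue[t]:
            keep = rng.random(len(arch)) < config.within_tissue_share
            n_private = int(np.sum(~keep))
            priv_slots = rng.choice(spare, size=n_private, replace=False, shuffle=False)
            ivs = (
                [iv for iv, k in zip(arch, keep) if k]
                + [slot_interval(int(k)) for k in priv_slots]
                + core
            )
            peaksets[line] = PeakSet(label=line, intervals=ivs)
            assignment_rows.append({"cell_line": line, "tissue": t})
    truth = pd.DataFrame(assignment_rows).set_index("cell_line")
    return peaksets, truth
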
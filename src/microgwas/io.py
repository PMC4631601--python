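"""Core containers and readers/writers for genotype, taxon-count and
covariate tables.

Conventions
-----------
* Genotype dosages are minor/alternate allele counts in {0, 1, 2}; missing
  calls are NaN.
* SNP positions are stored 0-based internally. VCF is 1-based on disk and
  converted on load/save; the dosage TSV stores the 1-based position in its
  ``pos`` column for consistency with VCF.
* Taxon counts are non-negative integers, one row per
  (individual, season, replicate), one column per taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TAXONOMY_LEVELS = ("phylum", "class", "order", "family", "genus")
# broader rank = smaller index
LEVEL_RANK = {lvl: i for i, lvl in enumerate(TAXONOMY_LEVELS)}

__all__ = [
    "TAXONOMY_LEVELS",
    "LEVEL_RANK",
    "GenotypeMatrix",
    "TaxaCountTable",
    "CovariateTable",
    "KinshipMatrix",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_vcf",
    "read_taxa_table",
    "write_taxa_table",
    "read_covariates",
    "write_covariates",
    "read_kinship",
    "write_kinship",
]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with per-SNP metadata.

    ``dosages``: DataFrame, index = individual ids, columns = SNP ids,
    values in {0, 1, 2, NaN}. ``snp_meta``: DataFrame indexed by SNP id
    with columns ``chrom`` and ``pos`` (0-based).
    """

    dosages: pd.DataFrame
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.index.has_duplicates:
            raise ValueError("duplicated individual ids in genotype matrix")
        if self.dosages.columns.has_duplicates:
            raise ValueError("duplicated SNP ids in genotype matrix")
        if list(self.snp_meta.index) != list(self.dosages.columns):
            self.snp_meta = self.snp_meta.loc[self.dosages.columns]
        if (self.snp_meta["pos"] < 0).any():
            raise ValueError("negative SNP positions")

    @property
    def individuals(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def values(self) -> np.ndarray:
        return self.dosages.to_numpy(dtype=float)

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        ids = list(ids)
        missing = set(ids) - set(self.dosages.index)
        if missing:
            raise KeyError(f"individuals absent from genotype matrix: {sorted(missing)[:5]}")
        return GenotypeMatrix(self.dosages.loc[ids], self.snp_meta.copy())

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        snp_ids = list(snp_ids)
        return GenotypeMatrix(self.dosages[snp_ids], self.snp_meta.loc[snp_ids])

    def maf(self) -> pd.Series:
        """Minor allele frequency per SNP, computed on non-missing calls."""
        f = self.dosages.mean(axis=0, skipna=True) / 2.0
        return np.minimum(f, 1.0 - f)

    def call_rate(self) -> pd.Series:
        return self.dosages.notna().mean(axis=0)


@dataclass
class TaxaCountTable:
    """Taxon read counts per (individual, season, replicate).

    ``counts``: DataFrame with a MultiIndex (individual, season, replicate)
    and one integer column per taxon. ``taxonomy``: DataFrame indexed by
    taxon with columns ``level`` (one of phylum..genus) and ``lineage``
    (semicolon-joined path from phylum down to the taxon itself).
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)) or np.isnan(vals).any():
                raise ValueError("taxon counts must be integers")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("taxon counts must be non-negative")
        bad = set(self.taxonomy["level"]) - set(TAXONOMY_LEVELS)
        if bad:
            raise ValueError(f"unknown taxonomy levels: {sorted(bad)}")
        missing = set(self.counts.columns) - set(self.taxonomy.index)
        if missing:
            raise ValueError(f"taxa without taxonomy annotation: {sorted(missing)[:5]}")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def individuals(self) -> list[str]:
        return sorted(set(self.counts.index.get_level_values("individual")))

    def seasons(self) -> list[str]:
        return sorted(set(self.counts.index.get_level_values("season")))

    def for_season(self, season: str) -> "TaxaCountTable":
        sel = self.counts.xs(season, level="season", drop_level=False)
        return TaxaCountTable(sel.copy(), self.taxonomy)


@dataclass
class CovariateTable:
    """Per-individual covariates: age (years), sex (F/M), collection_group."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicated individual ids in covariates")
        for col in ("age", "sex", "collection_group"):
            if col not in self.data.columns:
                raise ValueError(f"covariate table missing required column {col!r}")
        bad = set(self.data["sex"].astype(str)) - {"F", "M"}
        if bad:
            raise ValueError(f"sex must be F or M, got {sorted(bad)}")

    @property
    def individuals(self) -> list[str]:
        return list(self.data.index)

    def subset(self, ids) -> "CovariateTable":
        sub = self.data.loc[list(ids)]
        if sub.isna().any().any():
            raise ValueError("missing covariate values among analyzed individuals")
        return CovariateTable(sub)

    def sex_numeric(self) -> pd.Series:
        """Sex coded F=0, M=1 (documented sign convention)."""
        return (self.data["sex"].astype(str) == "M").astype(float)


@dataclass
class KinshipMatrix:
    """Symmetric PSD relatedness matrix aligned to individual ids."""

    values: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix must be square")
        if self.ids and len(self.ids) != n:
            raise ValueError("kinship ids do not match matrix dimension")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def align(self, ids) -> "KinshipMatrix":
        ids = list(ids)
        lookup = {iid: i for i, iid in enumerate(self.ids)}
        try:
            idx = np.array([lookup[i] for i in ids])
        except KeyError as exc:
            raise KeyError(f"individual {exc} absent from kinship matrix") from exc
        return KinshipMatrix(self.values[np.ix_(idx, idx)], ids)


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path: str | Path, format: str = "auto") -> GenotypeMatrix:
    """Read genotypes from a minimal VCF or a dosage TSV.

    VCF: biallelic records only (multi-allelic sites are rejected); only the
    GT field is interpreted and phasing is ignored; 1-based POS is converted
    to the internal 0-based convention.
    """
    path = Path(path)
    if format == "auto":
        name = path.name.removesuffix(".gz")
        format = "vcf" if name.endswith(".vcf") else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic record at {variant.CHROM}:{variant.POS} not supported"
            )
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        # cyvcf2 gt_types: 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
        gt = np.asarray(variant.gt_types, dtype=float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        ids.append(snp_id)
        chroms.append(variant.CHROM)
        poss.append(variant.POS - 1)  # to 0-based
        rows.append(dos)
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicated SNP ids")
    dosages = pd.DataFrame(
        np.asarray(rows).T if rows else np.empty((len(individuals), 0)),
        index=pd.Index(individuals, name="individual"),
        columns=ids,
    )
    meta = pd.DataFrame({"chrom": chroms, "pos": poss}, index=pd.Index(ids, name="snp"))
    return GenotypeMatrix(dosages, meta)


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    required = {"id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: dosage TSV must have columns {sorted(required)} + individuals")
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicated SNP ids")
    indiv_cols = [c for c in df.columns if c not in required]
    dos = df[indiv_cols].to_numpy(dtype=float)
    if np.nanmax(dos, initial=0) > 2 or np.nanmin(dos, initial=0) < 0:
        raise ValueError(f"{path}: dosages must lie in [0, 2]")
    dosages = pd.DataFrame(
        dos.T, index=pd.Index(indiv_cols, name="individual"), columns=list(df["id"])
    )
    meta = pd.DataFrame(
        {"chrom": df["chrom"].to_numpy(), "pos": df["pos"].to_numpy(dtype=np.int64) - 1},
        index=pd.Index(df["id"], name="snp"),
    )
    return GenotypeMatrix(dosages, meta)


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Dosage TSV: one row per SNP (id, chrom, pos 1-based, then individuals)."""
    out = pd.DataFrame(
        {
            "id": g.snp_ids,
            "chrom": g.snp_meta["chrom"].to_numpy(),
            "pos": g.snp_meta["pos"].to_numpy() + 1,
        }
    )
    dos = g.dosages.T.reset_index(drop=True)
    dos.columns = g.individuals
    out = pd.concat([out, dos], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype fields (REF=A, ALT=G)."""
    chroms: list[str] = []
    for c in g.snp_meta["chrom"]:
        if c not in chroms:
            chroms.append(c)
    order = np.lexsort(
        (g.snp_meta["pos"].to_numpy(), g.snp_meta["chrom"].map(chroms.index).to_numpy())
    )
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=microgwas\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.individuals) + "\n")
        dosages = g.values()
        for j in order:
            snp = g.snp_ids[j]
            chrom = g.snp_meta["chrom"].iloc[j]
            pos1 = int(g.snp_meta["pos"].iloc[j]) + 1
            calls = [
                "./." if np.isnan(d) else gt_code[float(d)] for d in dosages[:, j]
            ]
            fh.write(f"{chrom}\t{pos1}\t{snp}\tA\tG\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")


# ---------------------------------------------------------------------------
# taxa counts


def read_taxa_table(path: str | Path) -> TaxaCountTable:
    """Read a long-format taxon count TSV.

    Columns: individual, season, replicate, taxon, level, lineage, count.
    Counts must be non-negative integers; taxonomy levels must be one of
    phylum/class/order/family/genus.
    """
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "taxon": str})
    required = {"individual", "season", "replicate", "taxon", "level", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: taxa TSV must have columns {sorted(required)}")
    if (df["count"] < 0).any():
        bad = df.index[df["count"] < 0][0]
        raise ValueError(f"{path}: negative count at data row {bad + 1}")
    counts = df.pivot_table(
        index=["individual", "season", "replicate"],
        columns="taxon",
        values="count",
        aggfunc="sum",
        fill_value=0,
    ).astype(np.int64)
    counts.columns.name = None
    tax_cols = ["level"] + (["lineage"] if "lineage" in df.columns else [])
    taxonomy = df.drop_duplicates("taxon").set_index("taxon")[tax_cols]
    if "lineage" not in taxonomy.columns:
        taxonomy["lineage"] = taxonomy.index
    return TaxaCountTable(counts, taxonomy)


def write_taxa_table(table: TaxaCountTable, path: str | Path) -> None:
    long = (
        table.counts.stack()
        .rename("count")
        .reset_index()
        .rename(columns={"level_3": "taxon"})
    )
    if "taxon" not in long.columns:  # pandas names the stacked level after the column axis
        long = long.rename(columns={long.columns[3]: "taxon"})
    long["level"] = long["taxon"].map(table.taxonomy["level"])
    long["lineage"] = long["taxon"].map(table.taxonomy["lineage"])
    long.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# covariates & kinship


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", dtype={"individual": str})
    if "individual" not in df.columns:
        raise ValueError(f"{path}: covariate TSV must have an 'individual' column")
    df = df.set_index("individual")
    return CovariateTable(df)


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    cov.data.rename_axis("individual").to_csv(path, sep="\t")


def read_kinship(path: str | Path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index])


def write_kinship(k: KinshipMatrix, path: str | Path) -> None:
    pd.DataFrame(k.values, index=k.ids, columns=k.ids).to_csv(path, sep="\t")
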
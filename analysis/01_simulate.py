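#!/usr/bin/env python
"""Simulate the synthetic founder-population cohort.

Generates family-structured genotypes, covariates, two-season taxon count
tables with planted genetic/covariate effects, and per-cell-line DHS peak
files with one causal tissue. Writes everything (plus a machine-readable
truth sidecar) under the working directory for the downstream steps.
"""

import argparse
import json
from pathlib import Path

from microgwas.intervals import write_bed
from microgwas.io import (
    write_covariates,
    write_genotypes_tsv,
    write_kinship,
    write_taxa_table,
    write_vcf,
)
from microgwas.synthetic import (
    SimulationConfig,
    simulate_covariates,
    simulate_dhs_peaks,
    simulate_genotypes,
    simulate_taxa_counts,
)


def cohort_config(seed: int) -> SimulationConfig:
    """The cohort analysed by steps 02-06: one QTL taxon, one heritable
    taxon, one sex-dimorphic taxon, one age-associated taxon."""
    return SimulationConfig(
        n_individuals=200,
        n_snps=2000,
        n_families=40,
        family_size=5,
        n_taxa=40,
        reads_per_replicate=100_000,
        planted_effects=[("g__taxon000", "snp00100", 1.0)],
        taxon_h2={"g__taxon001": 0.6, "g__taxon000": 0.0},
        sex_effects={"g__taxon002": 1.0},
        age_effects={"g__taxon003": 0.5},
        n_tissues=5,
        n_cell_lines=20,
        seed=seed,
    )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--workdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    data = args.workdir / "data"
    data.mkdir(parents=True, exist_ok=True)
    cfg = cohort_config(args.seed)

    g, k_true = simulate_genotypes(cfg)
    cov = simulate_covariates(cfg, g.individuals)
    taxa, truth = simulate_taxa_counts(g, cov, cfg, true_kinship=k_true)
    peaks, tissue_truth = simulate_dhs_peaks(cfg, truth.causal_positions)

    write_genotypes_tsv(g, data / "genotypes.tsv")
    write_vcf(g, data / "genotypes.vcf")
    write_covariates(cov, data / "covariates.tsv")
    write_taxa_table(taxa, data / "taxa_counts.tsv")
    write_kinship(k_true, data / "kinship_pedigree.tsv")
    peak_dir = data / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for label, ps in peaks.items():
        write_bed(ps, peak_dir / f"{label}.bed")
    tissue_truth.to_csv(data / "cell_line_tissues.tsv", sep="\t")
    (data / "truth.json").write_text(
        json.dumps(
            {
                "causal": truth.causal,
                "h2": truth.h2,
                "causal_positions": truth.causal_positions,
                "causal_tissue": f"tissue{cfg.causal_tissue:02d}",
                "seed": args.seed,
            },
            indent=2,
        )
    )
    print(f"cohort: {cfg.n_individuals} individuals x {cfg.n_snps} SNPs, "
          f"{cfg.n_taxa} taxa x {cfg.seasons} seasons x {cfg.replicates_per_season} replicates")
    print(f"planted: QTL {cfg.planted_effects}, h2 {cfg.taxon_h2}, "
          f"sex {cfg.sex_effects}, age {cfg.age_effects}")
    print(f"wrote inputs to {data}")


if __name__ == "__main__":
    main()
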
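"""End-to-end driver: simulate -> preprocess -> QC/kinship -> GWAS + PVE ->
overlap test -> tissue enrichment, with a manifest for reproducibility.

All randomness flows from the single configured seed; rerunning with the
same config reproduces every output byte-for-byte (recorded as per-stage
file checksums in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import gwas as gw
from .genotypes import kinship_matrix, snp_qc
from .intervals import write_bed
from .io import write_covariates, write_genotypes_tsv, write_kinship, write_taxa_table
from .lmm import eigendecompose_kinship, estimate_pve
from .preprocess import preprocess_combined, preprocess_season
from .synthetic import (
    SimulationConfig,
    simulate_covariates,
    simulate_dhs_peaks,
    simulate_genotypes,
    simulate_taxa_counts,
)

log = logging.getLogger("microgwas")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Resolved thresholds for a full pipeline run.

    Defaults are the study's stated values: subsampling depth 2M reads,
    prevalence 75%, prune r 0.9, QC MAF 5% / call rate 95% / HWE 1e-3,
    analysis MAF 10%, q cutoffs {0.1, 0.2}, enrichment ladder with a
    50-SNP minimum bin.
    """

    out_dir: str = "results"
    seed: int = 0
    max_depth: int = 2_000_000
    prevalence: float = 0.75
    prune_r: float = 0.9
    qc_maf: float = 0.05
    call_rate: float = 0.95
    hwe_p: float = 0.001
    analysis_maf: float = 0.10
    q_cutoffs: tuple[float, float] = (0.1, 0.2)
    enrich_thresholds: tuple[float, ...] = enr.DEFAULT_THRESHOLDS
    min_bin_snps: int = 50
    n_perm_overlap: int = 10_000
    n_perm_enrich: int = 1000
    gwas_mode: str = "exact"
    n_gwas_traits: int | None = None  # cap for desk-scale demo runs
    simulation: SimulationConfig = field(default_factory=SimulationConfig)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run the synthetic end-to-end pipeline; returns the manifest dict."""
    t_start = time.time()
    out = Path(config.out_dir)
    (out / "data").mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "config": _jsonable(asdict(config))}

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"][name] = {"t": round(time.time() - t_start, 2)}

    sim = config.simulation
    stage("simulate")
    g, k_true = simulate_genotypes(sim)
    cov = simulate_covariates(sim, g.individuals)
    taxa, truth = simulate_taxa_counts(g, cov, sim, true_kinship=k_true)
    peaks, tissue_truth = simulate_dhs_peaks(sim, truth.causal_positions or {"none": 0})
    write_genotypes_tsv(g, out / "data" / "genotypes.tsv")
    write_covariates(cov, out / "data" / "covariates.tsv")
    write_taxa_table(taxa, out / "data" / "taxa_counts.tsv")
    peak_dir = out / "data" / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for label, ps in peaks.items():
        write_bed(ps, peak_dir / f"{label}.bed")
    tissue_truth.to_csv(out / "data" / "cell_line_tissues.tsv", sep="\t")

    stage("preprocess")
    seasons = sorted(set(taxa.counts.index.get_level_values("season")))
    per_season = {}
    for s in seasons:
        m, report = preprocess_season(
            taxa, s, config.max_depth, config.prevalence, config.prune_r, seed=config.seed
        )
        per_season[s] = m
        pd.DataFrame([r.__dict__ for r in report]).to_csv(
            out / f"pruned_pairs_{s}.tsv", sep="\t", index=False
        )
    if len(seasons) >= 2:
        combined, _ = preprocess_combined(
            taxa, (seasons[0], seasons[1]), config.max_depth,
            config.prevalence, config.prune_r, seed=config.seed,
        )
    else:
        combined = per_season[seasons[0]]
    combined.values.to_csv(out / "normalized_combined.tsv", sep="\t")

    stage("qc_kinship")
    g_qc, qc_report = snp_qc(g, config.qc_maf, config.call_rate, config.hwe_p)
    qc_report.to_frame().to_csv(out / "snp_qc_report.tsv", sep="\t", index=False)
    K = kinship_matrix(g_qc)
    write_kinship(K, out / "kinship.tsv")

    stage("gwas_pve")
    individuals = [i for i in combined.individuals if i in set(g_qc.individuals)]
    matrix = combined.values.loc[individuals]
    W = gw.build_covariate_design(cov, individuals)
    Kal = K.align(individuals)
    eig = eigendecompose_kinship(Kal)
    traits = list(matrix.columns)
    if config.n_gwas_traits is not None:
        traits = traits[: config.n_gwas_traits]
    results, pve_rows = {}, []
    for taxon in traits:
        y = gw.residualize(matrix[taxon].to_numpy(dtype=float), W)
        res = gw.run_gwas(
            pd.Series(y, index=individuals), g_qc, K, trait=taxon,
            maf_min=config.analysis_maf, mode=config.gwas_mode, K_eig=eig,
        )
        results[taxon] = res
        pve = estimate_pve(y, Kal)
        pve_rows.append(
            {"taxon": taxon, "pve": pve.pve, "se": pve.se, "nonzero": pve.nonzero}
        )
        res.table.to_csv(out / f"gwas_{taxon}.tsv", sep="\t")
    pve_df = pd.DataFrame(pve_rows).set_index("taxon")
    pve_df.to_csv(out / "pve.tsv", sep="\t")
    summary = pd.DataFrame(
        {
            "taxon": list(results),
            "n_snps": [r.n_snps for r in results.values()],
            "bonferroni_hits": [r.n_significant(None) for r in results.values()],
            "q10_hits": [r.n_significant(config.q_cutoffs[0]) for r in results.values()],
            "q20_hits": [r.n_significant(config.q_cutoffs[1]) for r in results.values()],
        }
    ).set_index("taxon")
    summary.to_csv(out / "gwas_summary.tsv", sep="\t")

    stage("overlap_test")
    hit_flags = np.array([results[t].has_hit(max(config.q_cutoffs)) for t in traits])
    nz_flags = pve_df.loc[traits, "nonzero"].to_numpy(dtype=bool)
    observed, emp_p = gw.herit_gwas_overlap_test(
        nz_flags, hit_flags, n_perm=config.n_perm_overlap, seed=config.seed
    )
    (out / "overlap_test.json").write_text(
        json.dumps({"observed_overlap": observed, "empirical_p": emp_p}, indent=2)
    )

    stage("tissue_enrichment")
    assignment = enr.cluster_cell_lines(peaks, k=sim.n_tissues)
    tpeaks = enr.tissue_peaks(assignment, peaks)
    enrich_out = {}
    # enrich the first trait with any hit (fall back to the first trait)
    target = next((t for t in traits if results[t].has_hit()), traits[0])
    res = results[target]
    mask = enr.snp_in_peak_mask(
        res.table["chrom"].tolist(), res.table["pos"].tolist(), tpeaks
    )
    try:
        profile = enr.enrichment_profile(
            res.table["p"].to_numpy(), mask, trait=target,
            thresholds=config.enrich_thresholds, min_snps=config.min_bin_snps,
        )
        profile.bins.to_csv(out / f"enrichment_{target}.tsv", sep="\t", index=False)
        sub = g_qc.subset_individuals(individuals)
        from .genotypes import analysis_maf_filter

        sub = analysis_maf_filter(sub, individuals, config.analysis_maf)
        y = gw.residualize(matrix[target].to_numpy(dtype=float), W)
        X = sub.values()
        perm = enr.enrichment_permutation_test(
            y, X, eig, mask, n_perm=config.n_perm_enrich,
            n_top=profile.n_top, seed=config.seed, mode="fast",
            actual_pvals=res.table["p"].to_numpy(),
        )
        header = "# empirical p-values are not corrected for multiple testing across tissues\n"
        with open(out / f"enrichment_p_{target}.tsv", "w") as fh:
            fh.write(header)
            perm.to_csv(fh, sep="\t")
        enrich_out = {"trait": target, "n_top": profile.n_top}
    except ValueError as exc:
        log.warning("enrichment skipped: %s", exc)
        enrich_out = {"trait": target, "skipped": str(exc)}
    manifest["enrichment"] = enrich_out

    stage("manifest")
    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest["checksums"] = checksums
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
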
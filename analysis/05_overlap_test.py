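#!/usr/bin/env python
"""Heritability-GWAS overlap permutation test.

Counts taxa that are both flagged heritable (PVE - SE > 0) and carry at
least one genome-wide hit (within-GWAS Bonferroni or q <= 0.2), then
permutes the heritability flags across taxa to get the null overlap
distribution and an empirical p-value.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from microgwas.gwas import herit_gwas_overlap_test


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--workdir", type=Path, default=Path("results/analysis"))
    ap.add_argument("--n-perm", type=int, default=10_000)
    args = ap.parse_args()
    wd = args.workdir

    pve = pd.read_csv(wd / "pve.tsv", sep="\t", index_col=0)
    summary = pd.read_csv(wd / "gwas_summary.tsv", sep="\t", index_col=0)
    taxa = [t for t in pve.index if t in summary.index]
    heritable = pve.loc[taxa, "nonzero"].astype(bool).to_numpy()
    hits = (
        summary.loc[taxa, ["bonferroni_hits", "q20_hits"]].sum(axis=1) > 0
    ).to_numpy()

    observed, p = herit_gwas_overlap_test(
        heritable, hits, n_perm=args.n_perm, seed=args.seed
    )
    out = {
        "n_taxa": len(taxa),
        "n_heritable": int(heritable.sum()),
        "n_with_hit": int(hits.sum()),
        "observed_overlap": observed,
        "empirical_p": p,
        "n_perm": args.n_perm,
    }
    (wd / "overlap_test.json").write_text(json.dumps(out, indent=2))
    print(f"{out['n_heritable']} heritable taxa, {out['n_with_hit']} with a "
          f"genome-wide hit, overlap {observed}; empirical p = {p:.4f} "
          f"({args.n_perm} permutations)")


if __name__ == "__main__":
    main()
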
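#!/usr/bin/env python
"""Co-conservation analysis: profile the conservation of SNP loci and
TSSs, reduce profiles to 19 logarithmic bins, cluster them (K-means, K=2)
into high/low conservation classes, and test whether the conservation
class of a SNP is associated with that of its eQTL target gene
(Yates-corrected chi-squared on the 2x2 interaction table), plus KS
comparisons of SNP vs TSS conservation.

Reads the files written by 01_simulate.py.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from coevoqtl.conservation_profiles import (
    average_pileup,
    bin_profile,
    chi_squared_yates,
    contingency_table,
    extract_profile,
    kmeans_cluster,
    ks_compare,
    label_centroids,
)
from coevoqtl.io_formats import read_bed, read_fixedstep_wig, read_pairs_table
from coevoqtl.prioritization import bh_threshold


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data-dir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/conservation"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    with open(args.data_dir / "conservation.wig") as fh:
        track = read_fixedstep_wig(fh)
    with open(args.data_dir / "snps.bed") as fh:
        snps = read_bed(fh)
    with open(args.data_dir / "tss.bed") as fh:
        genes = read_bed(fh)
    catalog = read_pairs_table(args.data_dir / "eqtl_catalog.tsv")

    snp_profiles = [extract_profile(track, s) for s in snps]
    tss_profiles = [extract_profile(track, g) for g in genes]

    pd.DataFrame(
        {
            "offset": np.arange(-1000, 1001),
            "snp_pileup": average_pileup(snp_profiles),
            "tss_pileup": average_pileup(tss_profiles),
        }
    ).to_csv(args.out_dir / "pileups.tsv", sep="\t", index=False)

    def classify(profiles, loci):
        model = label_centroids(
            kmeans_cluster([bin_profile(p) for p in profiles], seed=args.seed)
        )
        return model, dict(zip((iv.name for iv in loci), model.assignment_labels()))

    snp_model, snp_labels = classify(snp_profiles, snps)
    gene_model, gene_labels = classify(tss_profiles, genes)

    # the co-conservation question concerns detected eQTL interactions,
    # not every attempted test: take the BH-significant pairs
    interactions = catalog.loc[bh_threshold(catalog, alpha=0.05).rejected]
    table = contingency_table(interactions, snp_labels, gene_labels)
    chi2 = chi_squared_yates(table)
    d_stat, ks_p = ks_compare(
        [p.center for p in snp_profiles],
        [p.center for p in tss_profiles],
        alternative="a_less",
    )

    report = {
        "contingency": {
            "hc_snp_hc_gene": table.a,
            "lc_snp_hc_gene": table.b,
            "hc_snp_lc_gene": table.c,
            "lc_snp_lc_gene": table.d,
            "total": table.total,
        },
        "chi_squared": {"statistic": chi2.statistic, "p_value": chi2.p_value,
                        "yates_corrected": chi2.corrected},
        "ks_snp_less_conserved_than_tss": {"D": d_stat, "p_value": ks_p},
        "snp_centroids": snp_model.centroids.tolist(),
        "gene_centroids": gene_model.centroids.tolist(),
    }
    with open(args.out_dir / "co_conservation.json", "w") as fh:
        json.dump(report, fh, indent=1)

    print(f"profiles: {len(snp_profiles)} SNPs, {len(tss_profiles)} TSSs "
          "(2001 bases -> 19 bins)")
    print(f"{len(interactions)} significant interactions; table: "
          f"a={table.a} b={table.b} c={table.c} d={table.d}")
    print(f"chi-squared (Yates) = {chi2.statistic:.3f}, p = {chi2.p_value:.3g}")
    print(f"KS (SNP loci less conserved than TSSs): D = {d_stat:.3f}, "
          f"p = {ks_p:.3g}")
    print(f"written to {args.out_dir}/")


if __name__ == "__main__":
    main()
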
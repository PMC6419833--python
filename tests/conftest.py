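"""Shared fixtures: one desk-scale synthetic study, built once per session.

All fixtures are generated programmatically; nothing is read from disk.
"""

import numpy as np
import pytest

from coevoqtl.coevolution import score_pairs
from coevoqtl.phylo_matrices import build_similarity_matrix, extract_subalignments
from coevoqtl.synthetic_data import (
    SimulationConfig,
    random_species_tree,
    simulate_conservation_track,
    simulate_eqtl_catalog,
    simulate_msa,
)

DESK_SEED = 1


@pytest.fixture(scope="session")
def desk_study():
    """The default synthetic study: 20 species, 200 kb, 200 SNPs, 40 genes,
    30 planted coevolved pairs -- fully scored through the real pipeline."""
    cfg = SimulationConfig.default(seed=DESK_SEED)
    tree = random_species_tree(cfg.n_species, seed=cfg.seed, depth=cfg.tree_depth)
    blocks, manifest = simulate_msa(tree, cfg)
    track, labels = simulate_conservation_track(cfg)
    catalog = simulate_eqtl_catalog(cfg, labels)

    panel = tree.species
    regions = sorted(
        [cfg.locus_region(s) for s in cfg.snps]
        + [cfg.locus_region(g) for g in cfg.genes],
        key=lambda iv: (iv.chrom, iv.start),
    )
    subs = extract_subalignments(blocks, regions, panel)
    matrices = {s.interval.name: build_similarity_matrix(s) for s in subs}
    snp_matrices = {k: v for k, v in matrices.items() if k.startswith("rs")}
    gene_matrices = {k: v for k, v in matrices.items() if k.startswith("gene")}
    scored = score_pairs(snp_matrices, gene_matrices, catalog)
    catalog = catalog.merge(
        scored[["snp_id", "gene_id", "score"]], on=["snp_id", "gene_id"]
    )
    return {
        "config": cfg,
        "tree": tree,
        "blocks": blocks,
        "manifest": manifest,
        "track": track,
        "labels": labels,
        "catalog": catalog,
        "snp_matrices": snp_matrices,
        "gene_matrices": gene_matrices,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)
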
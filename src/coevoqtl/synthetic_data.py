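"""Synthetic genomes with planted co-conservation and coevolution structure.

The generator emulates the three inputs of the analysis:

* a species-tree-evolved multiple sequence alignment with per-region
  divergence-rate heterogeneity and per-species per-region dropout
  (missing alignments), where designated SNP-gene pairs share the same
  realized dropout pattern and the same per-branch rate multipliers so
  that their alignment-induced similarity matrices are correlated;
* a per-base conservation track whose high-conservation SNP loci sit in
  a locally accelerated dip inside a conserved flank, and whose
  high-conservation transcription start sites show conservation rising
  asymmetrically into the gene body;
* a cis-eQTL hypothesis catalog in which true associations carry small
  nominal p-values and the probability of being a true association is
  elevated for the planted coevolved pairs.

Everything is a deterministic function of ``SimulationConfig.seed``.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .io_formats import (
    ConservationTrack,
    GenomicInterval,
    MafSequence,
    MsaBlock,
    write_bed,
    write_fixedstep_wig,
    write_maf,
    write_pairs_table,
)

__all__ = [
    "SpeciesTree",
    "SimulationConfig",
    "random_species_tree",
    "simulate_msa",
    "simulate_conservation_track",
    "simulate_eqtl_catalog",
    "write_dataset",
]

_NUC = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass
class SpeciesTree:
    """A rooted binary species tree with branch lengths in expected
    substitutions per site, and one leaf designated as the reference."""

    tree: dendropy.Tree
    reference: str

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if self.reference not in labels:
            raise ValueError(f"reference {self.reference!r} is not a leaf")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")

    @property
    def species(self) -> tuple[str, ...]:
        """Panel order: reference first, then the rest sorted."""
        labels = sorted(leaf.taxon.label for leaf in self.tree.leaf_node_iter())
        labels.remove(self.reference)
        return (self.reference, *labels)

    @property
    def n_species(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def edges(self) -> tuple[list[tuple[int, int, float]], dict[str, int]]:
        """Preorder edge list as (parent_index, child_index, length) plus a
        species -> node-index map for the leaves. The root has index 0."""
        nodes = list(self.tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        out = []
        leaves: dict[str, int] = {}
        for node in nodes[1:]:
            length = node.edge.length or 0.0
            out.append((index[id(node.parent_node)], index[id(node)], length))
        for leaf in self.tree.leaf_node_iter():
            leaves[leaf.taxon.label] = index[id(leaf)]
        return out, leaves

    @classmethod
    def from_newick(cls, newick: str, reference: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree, reference)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick")


def random_species_tree(
    n_species: int = 20, seed: int = 0, depth: float = 0.5
) -> SpeciesTree:
    """Simulate a birth-death species tree scaled to a given root-to-tip
    depth (expected substitutions per site).

    The reference genome is the leaf renamed ``ref``; the remaining leaves
    are ``sp02`` ... ``spNN``.
    """
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=random.Random(int(seed)),
    )
    max_depth = max(l.distance_from_root() for l in tree.leaf_node_iter())
    scale = depth / max_depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    names = ["ref"] + [f"sp{i:02d}" for i in range(2, n_species + 1)]
    for leaf, name in zip(tree.leaf_node_iter(), names):
        leaf.taxon.label = name
    return SpeciesTree(tree, reference="ref")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with desk-scale defaults.

    The default scale (20 species, 200 kb, 200 SNPs, 40 genes) keeps the
    species-by-species matrix structure of the full analysis while staying
    minutes-scale. Regions used for similarity matrices are
    ``2 * region_flank + 1`` bases around each locus and never overlap.
    """

    seed: int = 0
    n_species: int = 20
    genome_length: int = 200_000
    chrom: str = "chr1"
    tree_depth: float = 0.5

    # loci (filled by generate_loci; may also be supplied directly)
    snps: list[GenomicInterval] = field(default_factory=list)
    genes: list[GenomicInterval] = field(default_factory=list)
    promoters: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)

    # alignment model
    region_flank: int = 100
    dropout_prob: float = 0.3
    background_dropout_prob: float = 0.1
    rate_sigma: float = 0.8
    background_block: int = 1000

    # conservation track model
    noise_sd: float = 0.15
    hc_fraction: float = 0.5
    snp_bump_amp: float = 0.8
    snp_bump_tau: float = 100.0
    snp_bump_halfwidth: int = 400
    snp_dip: float = 0.7
    tss_ramp_amp: float = 0.8
    tss_ramp_width: float = 150.0
    tss_ramp_halfwidth: int = 800

    # eQTL catalog model
    cis_window: int = 1_000_000
    base_true_fraction: float = 0.05
    planted_true_factor: float = 5.0
    hc_hc_true_factor: float = 3.0
    true_p_shape: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "dropout_prob",
            "background_dropout_prob",
            "hc_fraction",
            "base_true_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not (0.0 < self.true_p_shape <= 1.0):
            raise ConfigError("true_p_shape must be in (0, 1]")

    @property
    def region_width(self) -> int:
        return 2 * self.region_flank + 1

    @classmethod
    def default(
        cls,
        seed: int = 0,
        n_snps: int = 200,
        n_genes: int = 40,
        n_planted: int = 30,
        **overrides,
    ) -> "SimulationConfig":
        cfg = cls(seed=seed, **overrides)
        cfg.generate_loci(n_snps=n_snps, n_genes=n_genes, n_planted=n_planted)
        return cfg

    def generate_loci(
        self, n_snps: int = 200, n_genes: int = 40, n_planted: int = 30
    ) -> None:
        """Place SNPs, TSSs, and 1-3 promoters per gene on the genome so
        that no two matrix-extraction regions overlap; plant ``n_planted``
        coevolved (SNP, gene) pairs over distinct SNPs and distinct genes."""
        if n_planted > min(n_snps, n_genes):
            raise ConfigError("more planted pairs than distinct SNPs or genes")
        rng = np.random.default_rng([int(self.seed), 101])
        w = self.region_width
        gap = 50
        units: list[tuple[str, int]] = []  # (kind, span)
        n_prom = rng.integers(1, 4, size=n_genes)
        for g in range(n_genes):
            span = (1 + int(n_prom[g])) * (w + gap)
            units.append((f"gene{g:03d}", span))
        for s in range(n_snps):
            units.append((f"rs{s:04d}", w + gap))
        order = rng.permutation(len(units))
        used = sum(span for _, span in units) + 2 * (self.tss_ramp_halfwidth + 1)
        slack = self.genome_length - used
        if slack < 0:
            raise ConfigError("genome_length too small for the locus layout")
        extra = rng.multinomial(slack, np.full(len(units), 1.0 / len(units)))
        self.snps, self.genes, self.promoters = [], [], {}
        pos = self.tss_ramp_halfwidth + 1
        for j, k in enumerate(order):
            name, span = units[k]
            pos += int(extra[j])
            if name.startswith("rs"):
                center = pos + self.region_flank
                self.snps.append(
                    GenomicInterval(self.chrom, center, center + 1, ".", name)
                )
            else:
                g = int(name[4:])
                strand = "+" if rng.random() < 0.5 else "-"
                cursor = pos
                proms = []
                for p in range(int(n_prom[g])):
                    proms.append(
                        GenomicInterval(
                            self.chrom,
                            cursor,
                            cursor + w,
                            strand,
                            f"{name}_prom{p}",
                        )
                    )
                    cursor += w + gap
                center = cursor + self.region_flank
                self.genes.append(
                    GenomicInterval(self.chrom, center, center + 1, strand, name)
                )
                self.promoters[name] = proms
            pos += span
        self.snps.sort(key=lambda iv: iv.start)
        self.genes.sort(key=lambda iv: iv.start)
        snp_pick = rng.choice(len(self.snps), size=n_planted, replace=False)
        gene_pick = rng.choice(len(self.genes), size=n_planted, replace=False)
        self.planted_pairs = [
            (self.snps[i].name, self.genes[j].name)
            for i, j in zip(snp_pick, gene_pick)
        ]

    def locus_region(self, locus: GenomicInterval) -> GenomicInterval:
        """The matrix-extraction interval around a length-1 locus."""
        center = locus.start
        return GenomicInterval(
            locus.chrom,
            center - self.region_flank,
            center + self.region_flank + 1,
            locus.strand,
            locus.name,
        )


# ---------------------------------------------------------------------------
# alignment simulation


def _evolve_jc(
    parent: np.ndarray, distance: float, rng: np.random.Generator
) -> np.ndarray:
    """One Jukes-Cantor branch: substitute each site independently with
    probability 3/4 (1 - exp(-4/3 d))."""
    if distance <= 0:
        return parent.copy()
    p_sub = 0.75 * (1.0 - np.exp(-4.0 * distance / 3.0))
    mask = rng.random(parent.size) < p_sub
    child = parent.copy()
    if mask.any():
        shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        child[mask] = (child[mask] + shift) % 4
    return child


def _evolve_region(
    tree_edges: list[tuple[int, int, float]],
    leaf_index: dict[str, int],
    n_nodes: int,
    length: int,
    multipliers: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    root = rng.integers(0, 4, size=length, dtype=np.uint8)
    seqs: dict[int, np.ndarray] = {0: root}
    for k, (parent, child, bl) in enumerate(tree_edges):
        seqs[child] = _evolve_jc(seqs[parent], bl * float(multipliers[k]), rng)
    return {sp: seqs[idx] for sp, idx in leaf_index.items()}


def _codes_to_str(codes: np.ndarray) -> str:
    return _NUC[codes].tobytes().decode("ascii")


def simulate_msa(
    tree: SpeciesTree, config: SimulationConfig
) -> tuple[list[MsaBlock], dict]:
    """Evolve the genome down the species tree and emit sorted MSA blocks.

    Each locus region is one alignment block with its own per-branch rate
    multipliers (lognormal) and its own per-species dropout pattern;
    background sequence between regions is chunked into blocks with milder
    independent dropout. The two regions of a planted pair -- plus the
    gene's promoters -- share one realized dropout pattern and one
    multiplier vector, which is what makes their similarity matrices
    correlated. Returns the blocks and a ground-truth manifest.
    """
    if tree.n_species != config.n_species:
        raise ConfigError(
            f"tree has {tree.n_species} species, config expects {config.n_species}"
        )
    rng = np.random.default_rng([int(config.seed), 1])
    edges, leaf_index = tree.edges()
    n_edges = len(edges)
    panel = tree.species
    ref = tree.reference

    # assemble regions and shared-fate groups
    regions: list[tuple[GenomicInterval, str, str]] = []  # (iv, kind, group)
    gene_group = {g: f"solo:{g}" for g in (iv.name for iv in config.genes)}
    snp_group = {s: f"solo:{s}" for s in (iv.name for iv in config.snps)}
    for snp_name, gene_name in config.planted_pairs:
        if snp_name not in snp_group or gene_name not in gene_group:
            raise ConfigError(f"planted pair ({snp_name}, {gene_name}) references unknown loci")
        snp_group[snp_name] = gene_group[gene_name] = f"pair:{snp_name}:{gene_name}"
    for iv in config.snps:
        regions.append((config.locus_region(iv), "snp", snp_group[iv.name]))
    for iv in config.genes:
        regions.append((config.locus_region(iv), "gene", gene_group[iv.name]))
        for prom in config.promoters.get(iv.name, []):
            regions.append((prom, "promoter", gene_group[iv.name]))
    regions.sort(key=lambda r: r[0].start)
    for (a, _, ga), (b, _, gb) in zip(regions, regions[1:]):
        if a.overlaps(b) and ga != gb:
            raise ConfigError(
                f"regions {a.name} and {b.name} overlap with conflicting parameters"
            )
        if a.overlaps(b):
            raise ConfigError(f"regions {a.name} and {b.name} overlap")

    # one multiplier vector + dropout pattern per shared-fate group
    group_params: dict[str, tuple[np.ndarray, frozenset[str]]] = {}
    for _, _, group in regions:
        if group not in group_params:
            mult = rng.lognormal(0.0, config.rate_sigma, size=n_edges)
            dropped = frozenset(
                sp
                for sp in panel
                if sp != ref and rng.random() < config.dropout_prob
            )
            group_params[group] = (mult, dropped)

    blocks: list[MsaBlock] = []
    manifest_regions: list[dict] = []

    def emit(iv: GenomicInterval, mult, dropped, kind, group) -> None:
        seqs = _evolve_region(edges, leaf_index, 2 * len(panel) - 1, iv.length, mult, rng)
        rows = [
            MafSequence(
                src=f"{ref}.{iv.chrom}",
                start=iv.start,
                size=iv.length,
                strand="+",
                src_size=config.genome_length,
                text=_codes_to_str(seqs[ref]),
            )
        ]
        for sp in panel:
            if sp == ref or sp in dropped:
                continue
            rows.append(
                MafSequence(
                    src=f"{sp}.scaf1",
                    start=0,
                    size=iv.length,
                    strand="+",
                    src_size=iv.length,
                    text=_codes_to_str(seqs[sp]),
                )
            )
        blocks.append(MsaBlock(rows))
        manifest_regions.append(
            {
                "name": iv.name,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "kind": kind,
                "group": group,
                "dropped_species": sorted(dropped),
            }
        )

    cursor = 0
    bg_count = 0
    for iv, kind, group in regions:
        while cursor < iv.start:  # background gap before this region
            end = min(iv.start, cursor + config.background_block)
            bg = GenomicInterval(config.chrom, cursor, end, ".", f"bg{bg_count:04d}")
            mult = rng.lognormal(0.0, config.rate_sigma, size=n_edges)
            dropped = frozenset(
                sp
                for sp in panel
                if sp != ref and rng.random() < config.background_dropout_prob
            )
            emit(bg, mult, dropped, "background", f"solo:{bg.name}")
            bg_count += 1
            cursor = end
        mult, dropped = group_params[group]
        emit(iv, mult, dropped, kind, group)
        cursor = iv.end
    while cursor < config.genome_length:
        end = min(config.genome_length, cursor + config.background_block)
        bg = GenomicInterval(config.chrom, cursor, end, ".", f"bg{bg_count:04d}")
        mult = rng.lognormal(0.0, config.rate_sigma, size=n_edges)
        dropped = frozenset(
            sp
            for sp in panel
            if sp != ref and rng.random() < config.background_dropout_prob
        )
        emit(bg, mult, dropped, "background", f"solo:{bg.name}")
        bg_count += 1
        cursor = end

    manifest = {
        "seed": int(config.seed),
        "species": list(panel),
        "reference": ref,
        "chrom": config.chrom,
        "genome_length": config.genome_length,
        "region_flank": config.region_flank,
        "planted_pairs": [list(p) for p in config.planted_pairs],
        "snps": [{"name": iv.name, "pos": iv.start} for iv in config.snps],
        "genes": [
            {"name": iv.name, "tss": iv.start, "strand": iv.strand}
            for iv in config.genes
        ],
        "promoters": {
            g: [{"name": p.name, "start": p.start, "end": p.end} for p in ps]
            for g, ps in config.promoters.items()
        },
        "regions": manifest_regions,
    }
    return blocks, manifest


# ---------------------------------------------------------------------------
# conservation track simulation


def simulate_conservation_track(
    config: SimulationConfig,
) -> tuple[ConservationTrack, dict[str, dict[str, str]]]:
    """Generate a PhyloP-like per-base track plus ground-truth HC/LC labels.

    High-conservation SNPs get a symmetric positive flank bump with the
    locus itself pinned to a negative (accelerated) score; high-conservation
    TSSs get a logistic ramp of conservation rising across the TSS into the
    gene body (strand-oriented). Low-conservation loci are baseline noise.
    """
    rng = np.random.default_rng([int(config.seed), 2])
    n = config.genome_length
    scores = rng.normal(0.0, config.noise_sd, size=n)
    labels: dict[str, dict[str, str]] = {"snps": {}, "genes": {}}

    for iv in config.snps:
        if not (0 <= iv.start < n):
            raise ConfigError(f"SNP {iv.name} outside genome bounds")
        hc = rng.random() < config.hc_fraction
        labels["snps"][iv.name] = "high" if hc else "low"
        if not hc:
            continue
        hw = config.snp_bump_halfwidth
        lo, hi = max(0, iv.start - hw), min(n, iv.start + hw + 1)
        d = np.arange(lo, hi) - iv.start
        scores[lo:hi] += config.snp_bump_amp * np.exp(
            -np.abs(d) / config.snp_bump_tau
        )
        scores[iv.start] = -config.snp_dip  # accelerated locus inside conserved flank

    for iv in config.genes:
        if not (0 <= iv.start < n):
            raise ConfigError(f"gene {iv.name} outside genome bounds")
        hc = rng.random() < config.hc_fraction
        labels["genes"][iv.name] = "high" if hc else "low"
        if not hc:
            continue
        hw = config.tss_ramp_halfwidth
        lo, hi = max(0, iv.start - hw), min(n, iv.start + hw + 1)
        d = (np.arange(lo, hi) - iv.start).astype(float)
        if iv.strand == "-":
            d = -d
        scores[lo:hi] += config.tss_ramp_amp / (
            1.0 + np.exp(-d / config.tss_ramp_width)
        )

    track = ConservationTrack()
    track.add_run(config.chrom, 0, scores)
    return track, labels


# ---------------------------------------------------------------------------
# eQTL catalog simulation


def simulate_eqtl_catalog(
    config: SimulationConfig,
    labels: dict[str, dict[str, str]] | None = None,
) -> pd.DataFrame:
    """Simulate nominal p-values for every cis SNP-gene test.

    Each pair is true with probability ``base_true_fraction``, multiplied by
    ``planted_true_factor`` for planted coevolved pairs and by
    ``hc_hc_true_factor`` when both members are labeled high-conservation
    (capped at 0.9). Null pairs draw p ~ Uniform(0, 1); true pairs draw
    p = U**(1/a) with a = ``true_p_shape`` (a Beta(a, 1) small-p law).
    The returned catalog carries an ``is_true`` truth column.
    """
    rng = np.random.default_rng([int(config.seed), 3])
    planted = set(map(tuple, config.planted_pairs))
    rows = []
    for snp in config.snps:
        for gene in config.genes:
            if snp.chrom != gene.chrom:
                continue
            dist = abs(snp.start - gene.start)
            if dist > config.cis_window:
                continue
            rows.append((snp, gene, dist))
    for snp_name, gene_name in planted:
        if not any(s.name == snp_name and g.name == gene_name for s, g, _ in rows):
            raise ConfigError(
                f"planted pair ({snp_name}, {gene_name}) violates the cis window"
            )
    n = len(rows)
    p_true = np.full(n, config.base_true_fraction)
    for i, (snp, gene, _) in enumerate(rows):
        if (snp.name, gene.name) in planted:
            p_true[i] *= config.planted_true_factor
        if (
            labels is not None
            and labels["snps"].get(snp.name) == "high"
            and labels["genes"].get(gene.name) == "high"
        ):
            p_true[i] *= config.hc_hc_true_factor
    p_true = np.minimum(p_true, 0.9)
    is_true = rng.random(n) < p_true
    u = rng.random(n)
    pvals = np.where(is_true, u ** (1.0 / config.true_p_shape), u)
    df = pd.DataFrame(
        {
            "snp_id": [s.name for s, g, d in rows],
            "gene_id": [g.name for s, g, d in rows],
            "snp_chrom": [s.chrom for s, g, d in rows],
            "snp_pos": [s.start for s, g, d in rows],
            "gene_chrom": [g.chrom for s, g, d in rows],
            "tss_pos": [g.start for s, g, d in rows],
            "nominal_p": pvals,
            "distance": [float(d) for s, g, d in rows],
            "is_true": is_true,
            "planted": [(s.name, g.name) in planted for s, g, d in rows],
        }
    )
    return df


def write_dataset(
    out_dir: str | Path,
    blocks: list[MsaBlock],
    track: ConservationTrack,
    catalog: pd.DataFrame,
    config: SimulationConfig,
    manifest: dict,
    labels: dict | None = None,
) -> None:
    """Write the simulated study as MAF + WIG + BED + TSV + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "alignment.maf", "w") as fh:
        write_maf(blocks, fh)
    with open(out / "conservation.wig", "w") as fh:
        write_fixedstep_wig(track, fh)
    with open(out / "snps.bed", "w") as fh:
        write_bed(config.snps, fh)
    with open(out / "tss.bed", "w") as fh:
        write_bed(config.genes, fh)
    with open(out / "promoters.bed", "w") as fh:
        write_bed([p for ps in config.promoters.values() for p in ps], fh)
    write_pairs_table(catalog, out / "eqtl_catalog.tsv")
    truth = dict(manifest)
    if labels is not None:
        truth["conservation_labels"] = labels
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
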
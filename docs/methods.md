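# Methods

This note documents the models and procedures implemented in `coevoqtl`,
the choices made where the design was genuinely open, and what the
synthetic study does and does not establish.

## Overview

The pipeline asks two questions about SNP–gene pairs tested for cis-eQTL
association (SNP within 1 Mbp of the gene's TSS on the same chromosome):

1. **Co-conservation** — is the conservation class of a SNP locus
   associated with the conservation class of its target gene?
2. **Coevolution** — do the two loci's phylogenetic histories correlate,
   and can that correlation prioritize association tests?

Both questions are answered on synthetic data with planted ground truth;
the package also reads the standard formats (MAF, fixedStep WIG, BED,
TSV) so the same code runs on real alignment and conservation tracks.

## Conservation profiles and co-conservation

A locus's profile is the 2001 per-base PhyloP-like scores covering the
locus ±1000 bp (positive = conserved, negative = accelerated; 0 =
neutral). Profiles of minus-strand TSSs are reversed so "upstream" is
transcriptional; SNPs have no strand and use reference orientation. The
strand orientation of gene profiles is a package choice: the asymmetric
rising-into-the-gene-body centroid is only meaningful under it.

Profiles are reduced to 19 dimensions by logarithmic binning: the locus
alone in the center bin, bins doubling outward (2, 4, …, 256) and a
terminal 490-base bin per side. This layout is the unique doubling
scheme with a center bin of 1 that covers 1000 flanking bases in 9 bins
per side. Missing bases (track gaps, off-chromosome positions) are
excluded from bin means rather than imputed as 0, because 0 means
"neutral rate", not "no data"; an all-missing bin is NaN and is imputed
by the profile's own mean only at clustering time.

Binned profiles are clustered with Euclidean K-means, K = 2, best of 10
seeded restarts by within-cluster sum of squares. The centroid with the
larger mean over its 19 values is labeled *high conservation*; ties
break by center-bin value, then index (arbitrary but deterministic).

Detected eQTL interactions are cross-tabulated by (SNP class) × (gene
class) and tested with the 2×2 chi-squared test *with Yates continuity
correction* — each cell contributes (max(|O−E|−0.5, 0))²/E, df = 1. The
corrected form is the package default because it is the variant that
reproduces the reference statistic for this analysis (23.651 on the
(428, 7544, 1775, 40975) table; the uncorrected form gives ≈ 23.94).
Distribution comparisons use the two-sample Kolmogorov–Smirnov test;
`a_less` / `a_greater` denote one-sided alternatives about stochastic
ordering of the first sample.

## Similarity matrices

For an interval of length *L* (reference bases; alignment columns where
the reference is gapped are excluded) the similarity of species *i*, *j*
is

    S_ij = #{columns where i and j are present, ungapped, and identical} / L.

Comparison is case-insensitive; ambiguity codes (N, …) match nothing,
including themselves. A species with no alignment over the interval has
an all-zero row and column, and the diagonal holds each species'
presence fraction. The identity-fraction definition was chosen because
the score must be a match rate with a full-interval denominator so that
a missing alignment yields exactly 0 — the property the sparse
correlation keys on. No affine-gap or substitution-matrix scoring is
used; the definition is parameter-free.

Extraction over many (possibly overlapping) sorted intervals is a
single serial pass over the sorted alignment blocks. The interval width
around a locus (`region_flank`, default 100 bp each side) is a
parameter, not a constant, since matrix quality varies with sequence
length.

## Sparse correlation (bipartite mirrortree)

The coevolution score of two loci is the product-moment correlation of
their similarity matrices' off-diagonal upper triangles after dropping
every position where *both* entries are exactly 0.0. Exact equality is
deliberate: entries are rational counts/L, and exact zeros occur
precisely for absent or never-matching pairs, so no epsilon is needed.
The diagonal is excluded because it encodes presence, not pairwise
divergence, and would inflate the correlation.

The score is undefined when fewer than `min_entries` (default 3, since
any 2 points give |r| = 1) positions survive, or a retained vector is
constant. Undefined scores are excluded from histograms, KS
comparisons, and prioritized subsets (but their tests stay in the
full-catalog BH run); counts of undefined pairs are reported.

Why sparse: appending species that are absent in both matrices leaves
the sparse score unchanged but drags the full (classical mirrortree)
correlation upward — in the limit of shared absence the full correlation
approaches the *uncentered cosine* of the retained entries, a strongly
positive value for match-rate data regardless of the true relationship.
Shared missing data therefore masquerades as coevolution under full
correlation; the property tests assert both the invariance and the
inflation.

A gene with multiple promoters is scored against a SNP by the maximum
defined score over its promoters (single-promoter hypothesis). The
corresponding background must also take per-gene maxima, and being a
max-of-k it is shifted upward relative to the single-interval
background; the tests assert this dominance.

Negative scores are retained throughout, and rank correlation is not
used (the score is the classical product-moment form).

## BH prioritization and the β/γ identity

The step-up rule: sort nominal p-values ascending, find the largest K
with P₍K₎ < Kα/n (strict inequality; a `strict=False` flag gives the
conventional ≤ variant, which differs only on exact ties), reject the K
smallest, and report P = Kα/n as the significance threshold. Because
decimal ties like P₍K₎ = 0.03 vs 3·0.05/5 are not representable in
binary floats, the comparison is made on the common scale n·P₍K₎ vs
K·α with values within 1e-12 relative treated as tied.

For a prioritization that retains a fraction γ of all hypotheses and a
fraction β of the significant ones, the prioritized threshold satisfies
P′ = βKα/(γn), hence P′/P = β/γ: the threshold relaxes exactly when the
retained set is enriched for significant interactions. The package
verifies this identity to 1e-12 on constructed catalogs and reports
empirical β, γ, and the residual whenever truth labels exist.

Controls: uniform seeded downsampling (β ≈ γ, so the threshold is
stable up to the α/m granularity of an m-test subsample — small
catalogs are summarized by the median over many subsample seeds); and a
distance-matched subset, built deterministically as the largest
smallest-distance prefix whose mean distance stays at or below the
target (random matching would be an alternative; the prefix rule was
chosen for exact reproducibility).

## The synthetic study

The generator emulates the three inputs at desk scale. Defaults, chosen
once as a realistic minutes-scale configuration:

| parameter | default | meaning |
|---|---|---|
| `n_species` (l) | 20 | genomes in the alignment panel |
| `genome_length` | 200 kb | one chromosome |
| SNPs / genes / planted pairs | 200 / 40 / 30 | locus sets; planted pairs share evolutionary fate |
| `tree_depth` | 0.5 | expected substitutions/site, root to tip (birth–death tree) |
| `region_flank` | 100 bp | half-width of matrix-extraction intervals |
| `dropout_prob` | 0.3 | per-species per-region missing-alignment probability |
| `rate_sigma` | 0.8 | lognormal σ of per-branch per-region rate multipliers |
| `noise_sd` | 0.15 | conservation-track baseline noise |
| `snp_bump_amp` / `snp_dip` | 0.8 / 0.7 | conserved flank height / accelerated-locus depth |
| `tss_ramp_amp` / width | 0.8 / 150 bp | logistic conservation rise across the TSS |
| `base_true_fraction` | 0.05 | probability a cis pair is a true association |
| `planted_true_factor` | 5 | true-probability multiplier for planted pairs |
| `hc_hc_true_factor` | 3 | multiplier when both members are high-conservation |
| `true_p_shape` | 0.15 | Beta(a, 1) shape of true-pair p-values |

Sequences evolve down the species tree under a Jukes–Cantor
substitution process. Each region draws its own per-branch rate
multipliers and its own dropout pattern; a planted pair (and the gene's
promoters) shares one realized draw of both, which is what correlates
their similarity matrices. Both channels matter: shared dropout alone
would be erased by the co-zero exclusion, so shared rate multipliers
carry signal through the retained entries, while dropout differences
between non-planted regions decorrelate the background.

Consequences worth knowing when reading results on this generator:

* The background score distribution is broad and centered slightly
  below zero (independent dropout creates (0, x) discordances); planted
  pairs score near +1. Real backgrounds will sit elsewhere — the tests
  assert ordering and recovery, not absolute score values.
* The coevolution–eQTL link exists *only* through planting, so the
  all-true-eQTL vs background KS shift is diluted by the many
  non-coevolved true pairs; the planted-pair comparison is the sharp
  synthetic analog.
* Planted pairs are placed at random distances, so score prioritization
  barely reduces mean pair distance here; the distance-matched control
  consequently stays close to the full catalog.

Not emulated: indels and alignment error, recombination, LD among
SNPs, genotype-level association noise, tissue structure, and the
~10⁸-pair scale of a real all-pairs background. Passing tests therefore
show the machinery is correct and the planted effects recoverable, not
that real eQTL pairs coevolve.

## Problem sizes and determinism

The default test suite and the analysis scripts run the full pipeline
at the 20-species / 200 kb / 8000-test scale (seconds per step); the
downsampling-stability check uses a 10⁵-test catalog with 50 subsample
seeds. Every stochastic step takes an explicit seed, and identical
configuration + seed reproduces byte-identical simulator output; the
three simulators draw from independent seeded streams so regenerating
one artifact never perturbs another.
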
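"""Bipartite mirrortree coevolution scoring via sparse correlation of
similarity matrices.

Two genomic elements with correlated phylogenetic histories have similarity
matrices that rise and fall together across species pairs. The score of a
pair of elements is the product-moment correlation of their matrices'
off-diagonal upper triangles -- computed *sparsely*: any species-pair
position where both matrices are exactly 0 is dropped first. Exact zeros
arise precisely from missing or never-matching alignments, and keeping them
would let shared missing data masquerade as coevolution (full correlation
drifts toward +1 as co-zero species are added; sparse correlation is
invariant to them).

Scoring all pairs between s SNP elements and g gene elements over an
l-species panel costs O(s * g * l^2); a listed catalog of n pairs costs
O(n * l^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .phylo_matrices import SimilarityMatrix

__all__ = [
    "CoevolutionScore",
    "sparse_correlation",
    "full_correlation",
    "score_pairs",
    "promoter_max_score",
    "background_distribution",
]

TOO_FEW, ZERO_VAR, OK = "too_few_entries", "zero_variance", "none"


@dataclass(frozen=True)
class CoevolutionScore:
    """A coevolution score in [-1, 1], or undefined with a reason."""

    value: float | None
    n_retained: int
    undefined_reason: str = OK

    @property
    def defined(self) -> bool:
        return self.value is not None


def _check_panels(a: SimilarityMatrix, b: SimilarityMatrix) -> None:
    if a.species != b.species:
        raise ValueError("matrices use different species panels")


def _correlate(x: np.ndarray, y: np.ndarray, min_entries: int) -> CoevolutionScore:
    n = x.size
    if n < min_entries:
        return CoevolutionScore(None, n, TOO_FEW)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CoevolutionScore(None, n, ZERO_VAR)
    r = float(np.corrcoef(x, y)[0, 1])
    return CoevolutionScore(float(np.clip(r, -1.0, 1.0)), n)


def sparse_correlation(
    a: SimilarityMatrix, b: SimilarityMatrix, min_entries: int = 3
) -> CoevolutionScore:
    """Sparse correlation of two similarity matrices.

    Takes the l(l-1)/2 off-diagonal upper-triangle entry pairs, drops every
    position where both entries are exactly 0.0, and correlates what
    remains. Undefined when fewer than ``min_entries`` positions survive or
    a retained vector is constant.
    """
    _check_panels(a, b)
    x, y = a.upper_triangle(), b.upper_triangle()
    keep = ~((x == 0.0) & (y == 0.0))
    return _correlate(x[keep], y[keep], min_entries)


def full_correlation(
    a: SimilarityMatrix, b: SimilarityMatrix, min_entries: int = 3
) -> CoevolutionScore:
    """Classical mirrortree correlation: no co-zero exclusion."""
    _check_panels(a, b)
    return _correlate(a.upper_triangle(), b.upper_triangle(), min_entries)


def score_pairs(
    snp_matrices: Mapping[str, SimilarityMatrix],
    gene_matrices: Mapping[str, SimilarityMatrix],
    catalog: pd.DataFrame | None = None,
    min_entries: int = 3,
) -> pd.DataFrame:
    """Score SNP-gene pairs: the listed pairs of ``catalog`` (snp_id /
    gene_id columns), or all s x g combinations when ``catalog`` is None.

    Returns a DataFrame with snp_id, gene_id, score (NaN when undefined),
    n_retained, undefined_reason.
    """
    if catalog is not None:
        missing = sorted(
            {s for s in catalog["snp_id"] if s not in snp_matrices}
            | {g for g in catalog["gene_id"] if g not in gene_matrices}
        )
        if missing:
            raise ValueError(f"no similarity matrix for loci: {missing[:10]}")
        pairs = list(zip(catalog["snp_id"], catalog["gene_id"]))
    else:
        pairs = [(s, g) for s in snp_matrices for g in gene_matrices]
    rows = []
    for s, g in pairs:
        sc = sparse_correlation(snp_matrices[s], gene_matrices[g], min_entries)
        rows.append(
            (s, g, np.nan if sc.value is None else sc.value, sc.n_retained, sc.undefined_reason)
        )
    return pd.DataFrame(
        rows, columns=["snp_id", "gene_id", "score", "n_retained", "undefined_reason"]
    )


def promoter_max_score(
    snp_matrix: SimilarityMatrix,
    promoter_matrices: Iterable[SimilarityMatrix],
    min_entries: int = 3,
) -> CoevolutionScore:
    """Score a SNP against a gene via its promoters: the maximum defined
    sparse correlation over the gene's promoters (the single-promoter
    hypothesis); undefined only when every promoter score is undefined."""
    proms = list(promoter_matrices)
    if not proms:
        raise ValueError("promoter_max_score requires at least one promoter")
    scores = [sparse_correlation(snp_matrix, p, min_entries) for p in proms]
    defined = [s for s in scores if s.defined]
    if not defined:
        return scores[0]
    return max(defined, key=lambda s: s.value)


def background_distribution(
    snp_matrices: Mapping[str, SimilarityMatrix],
    gene_matrices: Mapping[str, Mapping[str, SimilarityMatrix] | SimilarityMatrix],
    mode: str = "gene",
    bins: int = 40,
    budget: int = 1_000_000,
    subsample: bool = False,
    seed: int = 0,
    min_entries: int = 3,
) -> dict:
    """Coevolution scores of all s x g SNP-gene combinations.

    ``mode="gene"`` expects one matrix per gene; ``mode="promoter_max"``
    expects a mapping gene -> {promoter: matrix} and applies the
    max-over-promoters rule (whose background shifts toward higher scores,
    being a max of several draws). When s*g exceeds ``budget`` the pairs
    are seeded-subsampled if ``subsample`` is set, otherwise refused.

    Returns a dict with the defined scores, histogram counts over fixed
    bin edges spanning [-1, 1], and the number of undefined pairs.
    """
    if mode not in ("gene", "promoter_max"):
        raise ValueError(f"unknown mode {mode!r}")
    all_pairs = [(s, g) for s in snp_matrices for g in gene_matrices]
    if len(all_pairs) > budget:
        if not subsample:
            raise ValueError(
                f"{len(all_pairs)} pairs exceed budget {budget}; "
                "pass subsample=True for a seeded subsample"
            )
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(all_pairs), size=budget, replace=False)
        all_pairs = [all_pairs[i] for i in sorted(idx)]
    scores = []
    n_undefined = 0
    for s, g in all_pairs:
        if mode == "gene":
            sc = sparse_correlation(snp_matrices[s], gene_matrices[g], min_entries)
        else:
            sc = promoter_max_score(
                snp_matrices[s], list(gene_matrices[g].values()), min_entries
            )
        if sc.defined:
            scores.append(sc.value)
        else:
            n_undefined += 1
    edges = np.linspace(-1.0, 1.0, bins + 1)
    counts, _ = np.histogram(scores, bins=edges)
    return {
        "scores": np.asarray(scores),
        "hist_counts": counts,
        "hist_edges": edges,
        "n_undefined": n_undefined,
        "n_pairs": len(all_pairs),
    }
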
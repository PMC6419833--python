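"""Reference-anchored subalignment extraction and species-by-species
similarity matrices.

For each genomic interval we take the alignment columns where the reference
species has a nucleotide (so interval length is well-defined in reference
bases) and score every unordered species pair by the fraction of interval
columns at which both species are present, ungapped, and carry the same
nucleotide (case-insensitive; ambiguity codes never match). A species with
no alignment over the interval yields a pairwise similarity of 0 against
everyone -- the exact-zero convention the sparse correlation relies on.

Extraction over many intervals is serial: one pass through the (sorted)
alignment blocks, however many (possibly overlapping) sorted intervals are
requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator
import warnings

import numpy as np

from .io_formats import GenomicInterval, MsaBlock

__all__ = [
    "SubAlignment",
    "SimilarityMatrix",
    "extract_subalignments",
    "pairwise_similarity",
    "build_similarity_matrix",
]

_VALID = np.frombuffer(b"ACGT", dtype=np.uint8)
_GAP = ord("-")


@dataclass
class SubAlignment:
    """Reference-anchored alignment columns for one interval.

    ``chars`` is (n_species, length) uint8 of uppercased characters with
    ``-`` where a species is gapped or absent; ``present`` marks columns
    covered by a block that includes the species.
    """

    interval: GenomicInterval
    species: tuple[str, ...]
    chars: np.ndarray
    present: np.ndarray

    def __post_init__(self) -> None:
        if self.chars.shape != (len(self.species), self.interval.length):
            raise ValueError("chars shape must be (n_species, interval length)")
        if self.present.shape != self.chars.shape:
            raise ValueError("presence mask shape mismatch")

    @property
    def n_species(self) -> int:
        return len(self.species)


def extract_subalignments(
    blocks: Iterable[MsaBlock],
    intervals: list[GenomicInterval],
    panel: tuple[str, ...] | list[str],
) -> list[SubAlignment]:
    """Extract every interval's subalignment in one pass over the blocks.

    Intervals must be sorted by (chrom, start); blocks must be sorted the
    same way (read_maf enforces this for MAF input). Species outside
    ``panel`` are ignored; intervals beyond the alignment extent come back
    all-absent with a warning. Overlapping intervals are allowed and each
    is still filled completely.
    """
    panel = tuple(panel)
    order = {sp: i for i, sp in enumerate(panel)}
    keys = [(iv.chrom, iv.start) for iv in intervals]
    if keys != sorted(keys):
        raise ValueError("intervals must be sorted by (chrom, start)")
    subs = [
        SubAlignment(
            interval=iv,
            species=panel,
            chars=np.full((len(panel), iv.length), _GAP, dtype=np.uint8),
            present=np.zeros((len(panel), iv.length), dtype=bool),
        )
        for iv in intervals
    ]
    i0 = 0  # first interval that might still receive columns
    for block in blocks:
        ref_iv = block.reference_interval
        bs, be = ref_iv.start, ref_iv.end
        # positions of reference (non-gap) columns within the block
        ref_text = np.frombuffer(
            block.reference.text.upper().encode("ascii"), dtype=np.uint8
        )
        ref_cols = np.flatnonzero(ref_text != _GAP)
        ref_pos = bs + np.arange(ref_cols.size)
        while i0 < len(intervals) and (
            intervals[i0].chrom < ref_iv.chrom
            or (intervals[i0].chrom == ref_iv.chrom and intervals[i0].end <= bs)
        ):
            i0 += 1
        for i in range(i0, len(intervals)):
            iv = intervals[i]
            if iv.chrom != ref_iv.chrom or iv.start >= be:
                break
            inside = (ref_pos >= iv.start) & (ref_pos < iv.end)
            if not inside.any():
                continue
            cols = ref_cols[inside]
            dest = ref_pos[inside] - iv.start
            for seq in block.sequences:
                sp = seq.species
                if sp not in order:
                    continue
                row = np.frombuffer(
                    seq.text.upper().encode("ascii"), dtype=np.uint8
                )
                subs[i].chars[order[sp], dest] = row[cols]
                subs[i].present[order[sp], dest] = True
    uncovered = [
        s.interval.name or f"{s.interval.chrom}:{s.interval.start}"
        for s in subs
        if not s.present.any()
    ]
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} interval(s) beyond alignment extent: "
            f"{uncovered[:5]}",
            stacklevel=2,
        )
    return subs


def pairwise_similarity(
    sub: SubAlignment, species_a: str, species_b: str
) -> float:
    """Fraction of interval columns where both species are present, ungapped,
    and identical (A/C/G/T only). Absence or a gap contributes 0."""
    try:
        ia = sub.species.index(species_a)
        ib = sub.species.index(species_b)
    except ValueError as exc:
        raise ValueError(f"species not in panel: {exc}") from exc
    return _pair_rate(sub, ia, ib)


def _pair_rate(sub: SubAlignment, ia: int, ib: int) -> float:
    a, b = sub.chars[ia], sub.chars[ib]
    valid = (
        sub.present[ia]
        & sub.present[ib]
        & np.isin(a, _VALID)
        & np.isin(b, _VALID)
    )
    matches = int(np.count_nonzero(valid & (a == b)))
    return matches / sub.interval.length


def build_similarity_matrix(sub: SubAlignment) -> "SimilarityMatrix":
    """Score all l(l-1)/2 species pairs over one interval.

    Diagonal entries hold each species' presence fraction over the interval
    (1 fully aligned, 0 absent). Complexity O(l^2 * interval length).
    """
    if sub.interval.length == 0:
        raise ValueError("empty interval")
    l = sub.n_species
    values = np.zeros((l, l))
    for i in range(l):
        values[i, i] = sub.present[i].mean()
        for j in range(i + 1, l):
            values[i, j] = values[j, i] = _pair_rate(sub, i, j)
    return SimilarityMatrix(species=sub.species, values=values)


@dataclass
class SimilarityMatrix:
    """Symmetric l x l matrix of pairwise sequence match rates in [0, 1].

    All matrices in a run share one fixed species panel order so that
    entries from different intervals are position-compatible.
    """

    species: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        l = len(self.species)
        if self.values.shape != (l, l):
            raise ValueError("matrix shape must match species panel")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")

    @property
    def l(self) -> int:
        return len(self.species)

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal upper-triangle entries in fixed (row-major) order."""
        iu = np.triu_indices(self.l, k=1)
        return self.values[iu]
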
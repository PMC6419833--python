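"""Readers and writers for the genomic text formats the pipeline touches.

All coordinates inside the package are 0-based half-open. Conversion to and
from 1-based conventions (the fixedStep WIG ``start`` field) happens here and
nowhere else. Missing conservation values are represented by NaN, which is
deliberately distinct from 0.0: a PhyloP-like score of 0 means a neutral rate
of evolution, not an absent measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "MafSequence",
    "MsaBlock",
    "ConservationTrack",
    "FormatError",
    "read_maf",
    "write_maf",
    "read_fixedstep_wig",
    "write_fixedstep_wig",
    "read_bed",
    "write_bed",
    "read_pairs_table",
    "write_pairs_table",
]

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A file did not conform to its declared format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval, optionally stranded and named."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class MafSequence:
    """One ``s`` line of a MAF block."""

    src: str  # "<species>.<contig>" in UCSC usage
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def contig(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) == 2 else parts[0]


@dataclass
class MsaBlock:
    """One alignment block of a multiple sequence alignment.

    The first sequence is the reference; its non-gap characters anchor the
    block to reference coordinates.
    """

    sequences: list[MafSequence]
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("MsaBlock requires at least one sequence")
        n = self.column_count
        for seq in self.sequences:
            if len(seq.text) != n:
                raise ValueError(
                    f"row length mismatch in block: {seq.src} has "
                    f"{len(seq.text)} columns, expected {n}"
                )
        ref = self.sequences[0]
        ungapped = sum(1 for c in ref.text if c != "-")
        if ungapped != ref.size:
            raise ValueError(
                f"reference row {ref.src}: {ungapped} non-gap characters "
                f"but declared size {ref.size}"
            )

    @property
    def column_count(self) -> int:
        return len(self.sequences[0].text)

    @property
    def reference(self) -> MafSequence:
        return self.sequences[0]

    @property
    def reference_species(self) -> str:
        return self.reference.species

    @property
    def reference_interval(self) -> GenomicInterval:
        ref = self.reference
        return GenomicInterval(ref.contig, ref.start, ref.start + ref.size)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s.species for s in self.sequences)

    def row(self, species: str) -> str | None:
        for seq in self.sequences:
            if seq.species == species:
                return seq.text
        return None


def read_maf(stream: IO[str]) -> Iterator[MsaBlock]:
    """Parse MAF text into blocks, in file order.

    Blocks must be sorted by (reference chromosome, start). The reference
    species is the species of the first ``s`` line of each block and must be
    the same in every block. Malformed rows raise :class:`FormatError` naming
    the offending line number.
    """
    pending_score = 0.0
    rows: list[MafSequence] = []
    row_line_no = 0
    blocks_ref: str | None = None
    prev_key: tuple[str, int] | None = None

    def flush() -> MsaBlock | None:
        nonlocal rows, blocks_ref, prev_key
        if not rows:
            return None
        try:
            block = MsaBlock(rows, score=pending_score)
        except ValueError as exc:
            raise FormatError(f"near line {row_line_no}: {exc}") from exc
        rows = []
        if blocks_ref is None:
            blocks_ref = block.reference_species
        elif block.reference_species != blocks_ref:
            raise FormatError(
                f"near line {row_line_no}: reference species changed from "
                f"{blocks_ref!r} to {block.reference_species!r}"
            )
        key = (block.reference_interval.chrom, block.reference_interval.start)
        if prev_key is not None and key < prev_key:
            raise FormatError(
                f"near line {row_line_no}: blocks not sorted by reference "
                f"coordinate ({key} after {prev_key})"
            )
        prev_key = key
        return block

    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if stripped.startswith("#") or stripped == "":
            block = flush()
            if block is not None:
                yield block
            continue
        fields = stripped.split()
        if fields[0] == "a":
            block = flush()
            if block is not None:
                yield block
            pending_score = 0.0
            for kv in fields[1:]:
                if kv.startswith("score="):
                    try:
                        pending_score = float(kv[len("score="):])
                    except ValueError as exc:
                        raise FormatError(
                            f"line {line_no}: bad score field {kv!r}"
                        ) from exc
        elif fields[0] == "s":
            if len(fields) != 7:
                raise FormatError(
                    f"line {line_no}: 's' line has {len(fields)} fields, "
                    "expected 7"
                )
            try:
                seq = MafSequence(
                    src=fields[1],
                    start=int(fields[2]),
                    size=int(fields[3]),
                    strand=fields[4],
                    src_size=int(fields[5]),
                    text=fields[6],
                )
            except ValueError as exc:
                raise FormatError(f"line {line_no}: {exc}") from exc
            rows.append(seq)
            row_line_no = line_no
        # other MAF line types (i, e, q, track) are ignored
    block = flush()
    if block is not None:
        yield block


def write_maf(blocks: Iterable[MsaBlock], stream: IO[str]) -> None:
    stream.write("##maf version=1\n")
    for block in blocks:
        stream.write(f"a score={block.score:g}\n")
        width = max(len(s.src) for s in block.sequences)
        for s in block.sequences:
            stream.write(
                f"s {s.src:<{width}} {s.start} {s.size} {s.strand} "
                f"{s.src_size} {s.text}\n"
            )
        stream.write("\n")


class ConservationTrack:
    """Per-base real-valued scores addressable by (chrom, 0-based position).

    Positive scores mark conservation, negative scores accelerated evolution.
    Uncovered positions read as NaN.
    """

    def __init__(self) -> None:
        self._runs: dict[str, list[tuple[int, np.ndarray]]] = {}

    def add_run(self, chrom: str, start: int, values: np.ndarray | list) -> None:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("run must be a nonempty 1-d array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("conservation scores must be finite")
        if start < 0:
            raise ValueError("run start must be >= 0")
        runs = self._runs.setdefault(chrom, [])
        for s0, v0 in runs:
            if start < s0 + v0.size and s0 < start + arr.size:
                raise FormatError(
                    f"overlapping runs on {chrom}: [{start},{start + arr.size})"
                    f" vs [{s0},{s0 + v0.size})"
                )
        runs.append((start, arr))
        runs.sort(key=lambda r: r[0])

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted(self._runs))

    def runs(self, chrom: str) -> list[tuple[int, np.ndarray]]:
        return list(self._runs.get(chrom, []))

    def get(self, chrom: str, pos: int) -> float:
        """Score at one position; NaN when uncovered."""
        for start, vals in self._runs.get(chrom, []):
            if start <= pos < start + vals.size:
                return float(vals[pos - start])
        return math.nan

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores over [start, end); uncovered positions are NaN.

        Negative coordinates (off the chromosome start) are permitted and
        read as NaN, which lets callers take fixed-width windows near edges.
        """
        if end <= start:
            raise ValueError("window requires start < end")
        out = np.full(end - start, np.nan)
        for s0, vals in self._runs.get(chrom, []):
            lo = max(start, s0)
            hi = min(end, s0 + vals.size)
            if lo < hi:
                out[lo - start : hi - start] = vals[lo - s0 : hi - s0]
        return out


def read_fixedstep_wig(stream: IO[str]) -> ConservationTrack:
    """Read a fixedStep WIG file with step=1 (span=1).

    WIG declares a 1-based start; positions are converted to 0-based here.
    """
    track = ConservationTrack()
    chrom: str | None = None
    start0: int | None = None
    buffer: list[float] = []

    def flush() -> None:
        nonlocal buffer
        if chrom is not None and buffer:
            track.add_run(chrom, start0, np.array(buffer))
        buffer = []

    for line_no, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("track"):
            continue
        if line.startswith("fixedStep"):
            flush()
            params = dict(
                kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
            )
            try:
                chrom = params["chrom"]
                start1 = int(params["start"])
            except (KeyError, ValueError) as exc:
                raise FormatError(
                    f"line {line_no}: bad fixedStep declaration"
                ) from exc
            step = int(params.get("step", 1))
            span = int(params.get("span", 1))
            if step != 1 or span != 1:
                raise FormatError(
                    f"line {line_no}: only step=1 span=1 fixedStep is "
                    f"supported (got step={step} span={span})"
                )
            if start1 < 1:
                raise FormatError(f"line {line_no}: WIG start is 1-based, got {start1}")
            start0 = start1 - 1
        elif line.startswith("variableStep"):
            raise FormatError(f"line {line_no}: variableStep WIG is not supported")
        else:
            if chrom is None:
                raise FormatError(
                    f"line {line_no}: data before any fixedStep declaration"
                )
            try:
                buffer.append(float(line))
            except ValueError as exc:
                raise FormatError(f"line {line_no}: bad value {line!r}") from exc
    flush()
    return track


def write_fixedstep_wig(track: ConservationTrack, stream: IO[str]) -> None:
    for chrom in track.chroms:
        for start, values in track.runs(chrom):
            stream.write(f"fixedStep chrom={chrom} start={start + 1} step=1\n")
            for v in values:
                stream.write(f"{v:.6g}\n")


def read_bed(stream: IO[str]) -> list[GenomicInterval]:
    """Read BED3/BED6 into 0-based half-open intervals."""
    intervals: list[GenomicInterval] = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise FormatError(f"line {line_no}: BED needs >= 3 columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"line {line_no}: non-integer coordinates") from exc
        name = fields[3] if len(fields) >= 4 else None
        strand = fields[5] if len(fields) >= 6 else "."
        if strand not in STRANDS:
            raise FormatError(f"line {line_no}: bad strand {strand!r}")
        try:
            intervals.append(GenomicInterval(chrom, start, end, strand, name))
        except ValueError as exc:
            raise FormatError(f"line {line_no}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], stream: IO[str]) -> None:
    for iv in intervals:
        if iv.name is None and iv.strand == ".":
            stream.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        else:
            name = iv.name if iv.name is not None else "."
            stream.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


PAIRS_COLUMNS = [
    "snp_id",
    "gene_id",
    "snp_chrom",
    "snp_pos",
    "gene_chrom",
    "tss_pos",
    "nominal_p",
]


def read_pairs_table(stream: IO[str] | str) -> pd.DataFrame:
    """Read a SNP-gene hypothesis catalog from TSV.

    Required columns: snp_id, gene_id, snp_chrom, snp_pos, gene_chrom,
    tss_pos, nominal_p. A ``score`` column is carried through when present.
    The pair distance |snp_pos - tss_pos| is computed for same-chromosome
    pairs and is NaN for inter-chromosomal ones.
    """
    df = pd.read_csv(stream, sep="\t")
    missing = [c for c in PAIRS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pairs table missing columns: {missing}")
    p = df["nominal_p"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        bad = df.index[(p < 0) | (p > 1) | ~np.isfinite(p)].tolist()[:5]
        raise ValueError(f"nominal_p outside [0, 1] at rows {bad}")
    same = df["snp_chrom"].to_numpy() == df["gene_chrom"].to_numpy()
    dist = np.abs(
        df["snp_pos"].to_numpy(dtype=float) - df["tss_pos"].to_numpy(dtype=float)
    )
    df["distance"] = np.where(same, dist, np.nan)
    return df


def write_pairs_table(df: pd.DataFrame, stream: IO[str] | str) -> None:
    df.to_csv(stream, sep="\t", index=False)
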
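"""AXT pairwise-alignment parsing and coordinate projection.

A pairwise genome alignment is, in practice, a collection of local
alignments between conserved regions, so a coordinate on the reference
genome (A) either falls inside some gapless aligned block — and projects
to a unique position on the target genome (B) — or it does not align at
all.  This module parses UCSC AXT records, decomposes each record into
maximal gapless blocks, indexes the blocks by reference interval, and
projects single coordinates.  Coordinates that fall outside every block
project to :data:`UNMAPPED` (``None``); that is a value, not an error,
and callers are expected to skip and count such boundaries.

Conventions
-----------
* AXT headers are 1-based inclusive; everything in memory is 0-based
  half-open.
* AXT gives query ('B') coordinates on the query strand.  Minus-strand
  records are normalised to B plus-strand coordinates at block
  decomposition time, which requires the B chromosome length (AXT does
  not carry it); pass ``b_sizes`` for such records.
* A coordinate exactly at a block's exclusive end is UNMAPPED: half-open
  lookups never guess an adjacent base.
* Where chained records overlap on A, point lookups resolve to the
  record with the highest alignment score, ties going to the record
  that appeared first in the file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "UNMAPPED",
    "AxtParseError",
    "AxtRecord",
    "AlignmentBlock",
    "BlockMap",
    "Projection",
    "parse_axt",
    "write_axt",
    "decompose_blocks",
    "project",
    "project_oracle",
]

UNMAPPED = None


class AxtParseError(ValueError):
    """Raised on malformed AXT input."""


@dataclass(frozen=True)
class AxtRecord:
    """One AXT alignment record, coordinates 0-based half-open.

    ``b_start``/``b_end`` remain on the query strand as in the file;
    strand normalisation happens in :func:`decompose_blocks`.
    """

    index: int
    a_chrom: str
    a_start: int
    a_end: int
    b_chrom: str
    b_start: int
    b_end: int
    strand: str
    score: int
    a_seq: str
    b_seq: str
    order: int = 0  # position in file, used for deterministic tie-breaks

    def __post_init__(self) -> None:
        if len(self.a_seq) != len(self.b_seq):
            raise AxtParseError(
                f"record {self.index}: gapped rows differ in length "
                f"({len(self.a_seq)} vs {len(self.b_seq)})"
            )


@dataclass(frozen=True)
class AlignmentBlock:
    """A maximal gapless aligned run.

    ``b_start`` is the smallest B plus-strand coordinate of the block.
    For ``b_strand == '+'`` column *k* pairs ``a_start + k`` with
    ``b_start + k``; for ``'-'`` it pairs with ``b_start + length-1 - k``.
    """

    a_chrom: str
    a_start: int
    b_chrom: str
    b_start: int
    length: int
    b_strand: str = "+"
    score: int = 0
    order: int = 0

    def b_coord(self, a_coord: int) -> int:
        off = a_coord - self.a_start
        if not 0 <= off < self.length:
            raise ValueError("coordinate outside block")
        if self.b_strand == "+":
            return self.b_start + off
        return self.b_start + self.length - 1 - off


@dataclass(frozen=True)
class Projection:
    """Full result of projecting one A coordinate."""

    b_chrom: str
    b_coord: int
    b_strand: str
    score: int
    order: int


def parse_axt(stream: IO[str] | Iterable[str]) -> list[AxtRecord]:
    """Parse an AXT stream into records.

    Each record is a 9-field header line, the gapped A row, the gapped B
    row, and a blank separator.  Header coordinates (1-based inclusive)
    are converted to 0-based half-open.
    """
    lines = [ln.rstrip("\n") for ln in stream]
    records: list[AxtRecord] = []
    i = 0
    order = 0
    while i < len(lines):
        if not lines[i].strip() or lines[i].startswith("#"):
            i += 1
            continue
        header = lines[i].split()
        if len(header) != 9:
            raise AxtParseError(
                f"header line {i + 1}: expected 9 fields, got {len(header)}"
            )
        if i + 2 >= len(lines):
            raise AxtParseError(f"record at line {i + 1}: truncated record")
        try:
            idx = int(header[0])
            a_start, a_end = int(header[2]), int(header[3])
            b_start, b_end = int(header[5]), int(header[6])
            score = int(header[8])
        except ValueError as exc:
            raise AxtParseError(f"header line {i + 1}: non-integer field") from exc
        strand = header[7]
        if strand not in ("+", "-"):
            raise AxtParseError(f"header line {i + 1}: bad strand {strand!r}")
        rec = AxtRecord(
            index=idx,
            a_chrom=header[1],
            a_start=a_start - 1,
            a_end=a_end,
            b_chrom=header[4],
            b_start=b_start - 1,
            b_end=b_end,
            strand=strand,
            score=score,
            a_seq=lines[i + 1].strip(),
            b_seq=lines[i + 2].strip(),
            order=order,
        )
        _check_spans(rec, line=i + 1)
        records.append(rec)
        order += 1
        i += 3
    return records


def _check_spans(rec: AxtRecord, line: int) -> None:
    a_len = sum(1 for c in rec.a_seq if c != "-")
    b_len = sum(1 for c in rec.b_seq if c != "-")
    if a_len != rec.a_end - rec.a_start:
        raise AxtParseError(
            f"record at line {line}: A row has {a_len} bases but header spans "
            f"{rec.a_end - rec.a_start}"
        )
    if b_len != rec.b_end - rec.b_start:
        raise AxtParseError(
            f"record at line {line}: B row has {b_len} bases but header spans "
            f"{rec.b_end - rec.b_start}"
        )


def write_axt(records: Sequence[AxtRecord], stream: IO[str]) -> None:
    """Serialize records back to AXT text (1-based inclusive headers)."""
    for rec in records:
        stream.write(
            f"{rec.index} {rec.a_chrom} {rec.a_start + 1} {rec.a_end} "
            f"{rec.b_chrom} {rec.b_start + 1} {rec.b_end} {rec.strand} {rec.score}\n"
        )
        stream.write(rec.a_seq + "\n")
        stream.write(rec.b_seq + "\n")
        stream.write("\n")


def decompose_blocks(
    rec: AxtRecord, b_sizes: Mapping[str, int] | None = None
) -> list[AlignmentBlock]:
    """Split a record into maximal gapless blocks.

    Gap columns advance exactly one genome's cursor; runs where neither
    row has a gap become blocks.  Minus-strand query coordinates are
    normalised to B plus-strand positions here (``b_sizes`` must then
    supply the B chromosome length).
    """
    if rec.strand == "-":
        if b_sizes is None or rec.b_chrom not in b_sizes:
            raise ValueError(
                f"record {rec.index}: '-' strand normalisation needs the size "
                f"of {rec.b_chrom}"
            )
        b_size = b_sizes[rec.b_chrom]
    else:
        b_size = 0  # unused

    blocks: list[AlignmentBlock] = []
    a_cur, b_cur = rec.a_start, rec.b_start  # b_cur on query strand
    run_a_start = run_bq_start = None
    run_len = 0

    def flush() -> None:
        nonlocal run_a_start, run_bq_start, run_len
        if run_len > 0:
            if rec.strand == "+":
                b_plus = run_bq_start
            else:
                # query-strand run [q, q+len) maps to plus-strand
                # [size - q - len, size - q)
                b_plus = b_size - run_bq_start - run_len
            blocks.append(
                AlignmentBlock(
                    a_chrom=rec.a_chrom,
                    a_start=run_a_start,
                    b_chrom=rec.b_chrom,
                    b_start=b_plus,
                    length=run_len,
                    b_strand=rec.strand,
                    score=rec.score,
                    order=rec.order,
                )
            )
        run_a_start = run_bq_start = None
        run_len = 0

    for ca, cb in zip(rec.a_seq, rec.b_seq):
        if ca == "-" and cb == "-":
            raise AxtParseError(f"record {rec.index}: double-gap column")
        if ca != "-" and cb != "-":
            if run_len == 0:
                run_a_start, run_bq_start = a_cur, b_cur
            run_len += 1
            a_cur += 1
            b_cur += 1
        elif ca == "-":
            flush()
            b_cur += 1
        else:
            flush()
            a_cur += 1
    flush()

    if a_cur != rec.a_end or b_cur != rec.b_end:
        raise AxtParseError(
            f"record {rec.index}: reconstructed spans ({a_cur}, {b_cur}) do not "
            f"match header ({rec.a_end}, {rec.b_end})"
        )
    return blocks


class BlockMap:
    """Interval-indexed collection of gapless blocks, keyed by A coordinate."""

    def __init__(self, blocks: Iterable[AlignmentBlock]):
        self.blocks: list[AlignmentBlock] = sorted(
            blocks, key=lambda b: (b.a_chrom, b.a_start, b.order)
        )
        self._trees: dict[str, IntervalTree] = {}
        for b in self.blocks:
            self._trees.setdefault(b.a_chrom, IntervalTree()).addi(
                b.a_start, b.a_start + b.length, b
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[AxtRecord],
        b_sizes: Mapping[str, int] | None = None,
    ) -> "BlockMap":
        blocks: list[AlignmentBlock] = []
        for rec in records:
            blocks.extend(decompose_blocks(rec, b_sizes=b_sizes))
        return cls(blocks)

    def lookup(self, a_chrom: str, a_coord: int) -> AlignmentBlock | None:
        """Best block covering a point: highest score, then earliest in file."""
        tree = self._trees.get(a_chrom)
        if tree is None:
            return None
        hits = tree[a_coord]
        if not hits:
            return None
        best = min(hits, key=lambda iv: (-iv.data.score, iv.data.order))
        return best.data

    def project_full(self, a_chrom: str, a_coord: int) -> Projection | None:
        block = self.lookup(a_chrom, a_coord)
        if block is None:
            return UNMAPPED
        return Projection(
            b_chrom=block.b_chrom,
            b_coord=block.b_coord(a_coord),
            b_strand=block.b_strand,
            score=block.score,
            order=block.order,
        )


def project(bmap: BlockMap, a_chrom: str, a_coord: int) -> int | None:
    """Project one A coordinate to a B plus-strand coordinate, or UNMAPPED."""
    p = bmap.project_full(a_chrom, a_coord)
    return UNMAPPED if p is UNMAPPED else p.b_coord


def project_oracle(
    rec: AxtRecord, a_coord: int, b_sizes: Mapping[str, int] | None = None
) -> int | None:
    """Reference projection by walking every alignment column.

    Builds the per-column coordinate pairing of a single record and reads
    the answer off it.  Intended for tests: same contract as
    :func:`project` restricted to one record, independent implementation.
    """
    if rec.strand == "-":
        if b_sizes is None or rec.b_chrom not in b_sizes:
            raise ValueError("'-' strand oracle needs the B chromosome size")
        b_size = b_sizes[rec.b_chrom]
    pairing: dict[int, int] = {}
    a_cur, b_cur = rec.a_start, rec.b_start
    for ca, cb in zip(rec.a_seq, rec.b_seq):
        if ca != "-" and cb != "-":
            if rec.strand == "+":
                pairing[a_cur] = b_cur
            else:
                pairing[a_cur] = b_size - 1 - b_cur
            a_cur += 1
            b_cur += 1
        elif ca == "-":
            b_cur += 1
        else:
            a_cur += 1
    return pairing.get(a_coord, UNMAPPED)
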
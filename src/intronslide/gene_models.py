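"""Gene annotation models: transcripts, introns, phases and splice sites.

Parses UCSC genePred annotation tables, derives introns from exon
structure, selects one canonical isoform per gene (the transcript with
the most introns), and computes intron-level annotations used downstream:
the intron phase (coding nucleotides upstream of the intron, modulo 3)
and the donor/acceptor splice-site dinucleotides.

All internal coordinates are 0-based half-open, genePred's native
convention.  An intron occupies ``[start, end)``; its donor dinucleotide
is the first two intronic bases and its acceptor the last two, both read
in the transcription direction (reverse-complemented for minus-strand
transcripts).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import reverse_complement

__all__ = [
    "Transcript",
    "Intron",
    "SpliceSites",
    "GenePredParseError",
    "parse_genepred",
    "write_genepred",
    "extract_introns",
    "select_canonical",
    "canonical_by_gene",
    "intron_phase",
    "splice_dinucleotides",
    "load_fasta",
    "write_fasta",
]


class GenePredParseError(ValueError):
    """Raised when a genePred table row cannot be parsed."""


@dataclass(frozen=True)
class Transcript:
    """One transcript model: exon structure plus optional CDS.

    ``exons`` is an ascending list of non-overlapping ``(start, end)``
    genomic intervals (0-based half-open).  ``cds_start``/``cds_end``
    are ``None`` for non-coding transcripts (genePred encodes these as
    ``cdsStart == cdsEnd``).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty/inverted exon ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start/cds_end must both be set or both absent")
        if self.cds_start is not None:
            if not (self.exons[0][0] <= self.cds_start < self.cds_end <= self.exons[-1][1]):
                raise ValueError("CDS interval outside transcript span")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None


@dataclass(frozen=True)
class Intron:
    """One intron of a transcript; ``index`` counts 5'→3' in transcription order."""

    transcript_id: str
    index: int
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty intron [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SpliceSites:
    """Donor/acceptor dinucleotides in transcription orientation."""

    donor: str
    acceptor: str

    def __post_init__(self) -> None:
        for s in (self.donor, self.acceptor):
            if len(s) != 2 or any(c not in "ACGTN" for c in s):
                raise ValueError(f"bad splice dinucleotide {s!r}")

    @property
    def canonical(self) -> bool:
        return self.donor == "GT" and self.acceptor == "AG"


# genePred column layouts.  The "plain" dialect is the 10-column core or the
# 15-column extended form; the "binned" dialect (UCSC database dumps) carries
# a leading integer bin column.
_PLAIN_COUNTS = {10, 15}
_BINNED_COUNTS = {11, 16}


def _parse_int_list(text: str, lineno: int, what: str) -> list[int]:
    items = [x for x in text.strip().split(",") if x != ""]
    try:
        return [int(x) for x in items]
    except ValueError as exc:
        raise GenePredParseError(f"line {lineno}: bad {what} list {text!r}") from exc


def parse_genepred(stream: IO[str] | Iterable[str], dialect: str = "auto") -> list[Transcript]:
    """Parse a genePred table into :class:`Transcript` records.

    Parameters
    ----------
    stream:
        Text stream or iterable of lines.
    dialect:
        ``"plain"`` (10/15 columns), ``"binned"`` (leading bin column,
        11/16 columns) or ``"auto"`` to detect from the column count.

    genePred coordinates are already 0-based half-open and are preserved
    verbatim.  Rows with ``cdsStart == cdsEnd`` are non-coding.  Genes are
    identified by the ``name2`` field when the extended form provides it;
    otherwise each transcript forms its own singleton gene.
    """
    if dialect not in ("auto", "plain", "binned"):
        raise ValueError(f"unknown dialect {dialect!r}")
    transcripts: list[Transcript] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        n = len(fields)
        if dialect == "auto":
            if n in _PLAIN_COUNTS:
                row_dialect = "plain"
            elif n in _BINNED_COUNTS:
                row_dialect = "binned"
            else:
                raise GenePredParseError(
                    f"line {lineno}: {n} columns is not a recognised genePred layout"
                )
        else:
            row_dialect = dialect
        if row_dialect == "binned":
            if n not in _BINNED_COUNTS:
                raise GenePredParseError(
                    f"line {lineno}: expected {sorted(_BINNED_COUNTS)} columns, got {n}"
                )
            fields = fields[1:]
        elif n not in _PLAIN_COUNTS:
            raise GenePredParseError(
                f"line {lineno}: expected {sorted(_PLAIN_COUNTS)} columns, got {n}"
            )

        name, chrom, strand = fields[0], fields[1], fields[2]
        try:
            cds_start, cds_end = int(fields[5]), int(fields[6])
            exon_count = int(fields[7])
        except ValueError as exc:
            raise GenePredParseError(f"line {lineno}: non-integer coordinate field") from exc
        starts = _parse_int_list(fields[8], lineno, "exonStarts")
        ends = _parse_int_list(fields[9], lineno, "exonEnds")
        if len(starts) != len(ends):
            raise GenePredParseError(
                f"line {lineno}: exonStarts has {len(starts)} items but exonEnds has {len(ends)}"
            )
        if len(starts) != exon_count:
            raise GenePredParseError(
                f"line {lineno}: exonCount {exon_count} does not match {len(starts)} exons"
            )
        gene_id = fields[11] if len(fields) >= 12 and fields[11] else name
        coding = cds_start != cds_end
        try:
            transcripts.append(
                Transcript(
                    transcript_id=name,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(zip(starts, ends)),
                    cds_start=cds_start if coding else None,
                    cds_end=cds_end if coding else None,
                )
            )
        except ValueError as exc:
            raise GenePredParseError(f"line {lineno}: {exc}") from exc
    return transcripts


def write_genepred(transcripts: Sequence[Transcript], stream: IO[str]) -> None:
    """Serialize transcripts in the extended 15-column plain genePred dialect."""
    for t in sorted(transcripts, key=lambda t: (t.chrom, t.span[0], t.transcript_id)):
        tx_start, tx_end = t.span
        cds_start = t.cds_start if t.cds_start is not None else tx_end
        cds_end = t.cds_end if t.cds_end is not None else tx_end
        starts = "".join(f"{s}," for s, _ in t.exons)
        ends = "".join(f"{e}," for _, e in t.exons)
        frames = "".join("-1," for _ in t.exons)
        stream.write(
            "\t".join(
                [
                    t.transcript_id,
                    t.chrom,
                    t.strand,
                    str(tx_start),
                    str(tx_end),
                    str(cds_start),
                    str(cds_end),
                    str(len(t.exons)),
                    starts,
                    ends,
                    "0",
                    t.gene_id,
                    "none",
                    "none",
                    frames,
                ]
            )
            + "\n"
        )


def extract_introns(t: Transcript) -> list[Intron]:
    """Return the transcript's introns in transcription order.

    Intron *k* occupies the gap ``[exon_k.end, exon_{k+1}.start)`` in
    genomic order; for minus-strand transcripts indices run in reversed
    genomic order so index 0 is always the 5'-most intron.
    """
    gaps = [
        (self_end, next_start)
        for (_, self_end), (next_start, _) in zip(t.exons, t.exons[1:])
    ]
    if t.strand == "-":
        gaps = gaps[::-1]
    return [
        Intron(t.transcript_id, i, t.chrom, t.strand, s, e)
        for i, (s, e) in enumerate(gaps)
    ]


def select_canonical(transcripts: Sequence[Transcript]) -> Transcript:
    """Pick a gene's canonical isoform: the transcript with the most introns.

    Ties are broken deterministically by larger summed exon length, then by
    lexicographically smallest transcript id.
    """
    if not transcripts:
        raise ValueError("select_canonical requires a non-empty isoform list")
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) > 1:
        raise ValueError(f"isoforms span multiple genes: {sorted(gene_ids)}")
    return min(
        transcripts,
        key=lambda t: (-t.n_introns, -t.exon_length, t.transcript_id),
    )


def canonical_by_gene(transcripts: Iterable[Transcript]) -> list[Transcript]:
    """Group transcripts by gene_id and return one canonical isoform per gene."""
    groups: dict[str, list[Transcript]] = defaultdict(list)
    for t in transcripts:
        groups[t.gene_id].append(t)
    return [select_canonical(groups[g]) for g in sorted(groups)]


def intron_phase(t: Transcript, intron_index: int) -> int | None:
    """Phase of an intron: coding nucleotides upstream of it, modulo 3.

    Returns ``None`` (undefined) for non-coding transcripts and for introns
    lying outside the CDS span, e.g. in a UTR.
    """
    introns = extract_introns(t)
    if not 0 <= intron_index < len(introns):
        raise IndexError(f"intron index {intron_index} out of range for {t.transcript_id}")
    if not t.is_coding:
        return None
    intron = introns[intron_index]
    if intron.end <= t.cds_start or intron.start >= t.cds_end:
        return None
    coding = 0
    for s, e in t.exons:
        lo, hi = max(s, t.cds_start), min(e, t.cds_end)
        if hi <= lo:
            continue
        if t.strand == "+":
            # coding bases transcribed before the intron lie left of its start
            coding += max(0, min(hi, intron.start) - lo)
        else:
            coding += max(0, hi - max(lo, intron.end))
    return coding % 3


def splice_dinucleotides(genome: Mapping[str, str], intron: Intron) -> SpliceSites:
    """Donor and acceptor dinucleotides of an intron, transcription-oriented.

    ``genome`` maps chromosome names to sequences.  For minus-strand
    introns both dinucleotides are reverse-complemented from the genomic
    slice, so a canonical intron reads GT..AG regardless of strand.
    """
    if intron.chrom not in genome:
        raise KeyError(f"chromosome {intron.chrom!r} absent from sequence store")
    seq = genome[intron.chrom]
    if intron.start < 0 or intron.end > len(seq):
        raise ValueError(
            f"intron [{intron.start}, {intron.end}) outside chromosome "
            f"{intron.chrom} of length {len(seq)}"
        )
    left = str(seq[intron.start : intron.start + 2]).upper()
    right = str(seq[intron.end - 2 : intron.end]).upper()
    if intron.strand == "+":
        donor, acceptor = left, right
    else:
        donor, acceptor = reverse_complement(right), reverse_complement(left)
    return SpliceSites(donor=donor, acceptor=acceptor)


def load_fasta(path: str) -> dict[str, str]:
    """Load a FASTA file into a plain chrom → sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
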
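"""Synthetic homologous genome pairs with planted boundary-shift events.

Real searches for intron sliding need two assembled genomes, their gene
annotations and a whole-genome pairwise alignment.  This module builds
all of that at desk scale from a single ancestor: genome B is derived
from genome A by per-site substitutions, intergenic indels and a set of
*planted* exon–intron boundary changes whose exact signed deltas are
recorded in a truth ledger.  Because every edit is known, the emitted
AXT alignment is exact rather than heuristically re-aligned, and the
detector's output can be checked event-for-event against the ledger.

Planted mechanisms mirror the two classical scenarios for sliding:

``mutation``
    The annotated boundaries move by *d* and at most four genomic sites
    are edited so the relocated intron again carries canonical GT–AG
    dinucleotides (a series of point mutations creating new splice
    sites).
``cut_paste``
    The intron sequence block itself moves by *d* with the displaced
    exonic bases hopping across it, so the spliced transcript sequence
    is unchanged while the intron phase shifts.

Both mechanisms preserve sequence length, so the alignment stays
gapless at the planted locus.  Non-equal plantings move the two
boundaries independently (mutation-style site edits).

Substitutions are kept away from annotated boundaries and from planted
gene bodies so planted events are the only boundary-affecting
differences; indels are intergenic by default for the same reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignment_projection import AlignmentBlock, AxtRecord, BlockMap, write_axt
from .gene_models import (
    Intron,
    Transcript,
    extract_introns,
    intron_phase,
    splice_dinucleotides,
    write_fasta,
    write_genepred,
)

__all__ = [
    "SimParams",
    "TruthRecord",
    "SyntheticDataset",
    "Ancestor",
    "generate_ancestor",
    "derive_genome_b",
    "generate_dataset",
    "plan_plantings",
    "emit_dataset",
    "read_truth",
    "build_coordinate_example",
    "build_background_example",
    "BACKGROUND_SPACER",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Fixed 20-nt spacer standing in for the elided intron interior of the
#: worked donor/acceptor example (the example prints only the boundary
#: sequence; the spacer makes it executable).
BACKGROUND_SPACER = "ACGTACGTACGTACGTACGT"


@dataclass
class SimParams:
    """Generator configuration.

    Planted slidings are ``(gene_index, intron_index, signed_shift_bp,
    mechanism)`` with mechanism in ``{"mutation", "cut_paste"}``;
    planted non-equal shifts are ``(gene_index, intron_index,
    delta_start, delta_end)``.  Indices are transcription-order intron
    indices of the gene's canonical isoform.  Lengths are in bp, rates
    are per-site probabilities.
    """

    n_genes: int = 20
    n_chroms: int = 1
    introns_per_gene: tuple[int, int] = (2, 5)
    exon_len: tuple[int, int] = (60, 180)
    intron_len: tuple[int, int] = (80, 300)
    intergenic_len: tuple[int, int] = (200, 400)
    minus_strand_fraction: float = 0.3
    extra_isoform_prob: float = 0.7
    substitution_rate: float = 0.02
    indel_rate: float = 0.0005
    indel_len: tuple[int, int] = (1, 10)
    genic_indels: bool = False
    planted_slidings: list[tuple[int, int, int, str]] = field(default_factory=list)
    planted_nonequal: list[tuple[int, int, int, int]] = field(default_factory=list)
    unaligned_fraction: float = 0.0
    decoy_tsl_fraction: float = 0.0
    planted_low_tsl: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("substitution_rate", "indel_rate", "unaligned_fraction",
                     "decoy_tsl_fraction", "minus_strand_fraction",
                     "extra_isoform_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1 or self.n_chroms < 1:
            raise ValueError("need at least one gene and one chromosome")
        targets = set()
        for g, i, d, mech in self.planted_slidings:
            if d == 0:
                raise ValueError("planted sliding shift must be nonzero")
            if mech not in ("mutation", "cut_paste"):
                raise ValueError(f"unknown mechanism {mech!r}")
            targets.add(g)
        for g, i, ds, de in self.planted_nonequal:
            if ds == de:
                raise ValueError("planted non-equal shift must have unequal deltas")
            targets.add(g)
        n_planted = len(self.planted_slidings) + len(self.planted_nonequal)
        if len(targets) != n_planted:
            raise ValueError("planting targets must hit distinct genes")
        for g in targets:
            if not 0 <= g < self.n_genes:
                raise ValueError(f"planting target gene {g} out of range")


@dataclass(frozen=True)
class TruthRecord:
    """One planted event as the detector should report it."""

    gene_id: str
    a_transcript: str
    b_transcript: str
    chrom_a: str
    intron_index: int
    kind: str  # SLIDING | NONEQUAL
    delta_start: int
    delta_end: int
    mechanism: str
    a_donor: str
    a_acceptor: str
    b_donor: str
    b_acceptor: str
    a_phase: int | None
    b_phase: int | None


@dataclass
class Ancestor:
    genome: dict[str, str]
    transcripts: list[Transcript]
    canonical: list[Transcript]  # indexed by gene index
    params: SimParams


@dataclass
class SyntheticDataset:
    genome_a: dict[str, str]
    genome_b: dict[str, str]
    transcripts_a: list[Transcript]
    transcripts_b: list[Transcript]
    axt_records: list[AxtRecord]
    tsl: dict[str, str]
    truth: list[TruthRecord]
    expected_skipped: int
    params: SimParams | None = None

    def block_map(self) -> BlockMap:
        return BlockMap.from_records(self.axt_records)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _b_chrom(a_chrom: str) -> str:
    return a_chrom.replace("chrA", "chrB")


def generate_ancestor(params: SimParams) -> Ancestor:
    """Build genome A: genes with canonical GT–AG introns by construction.

    Each gene gets a full-length isoform plus, with probability
    ``extra_isoform_prob``, a truncated isoform with fewer introns, so
    canonical-isoform selection is exercised.  All transcripts are coding
    over their full span.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    seq_rng, struct_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    genome: dict[str, list[str]] = {}
    lengths: dict[str, int] = {}
    transcripts: list[Transcript] = []
    canonical: list[Transcript] = []

    chrom_of_gene = [g % params.n_chroms for g in range(params.n_genes)]
    for c in range(params.n_chroms):
        genome[f"chrA{c + 1}"] = []
        lengths[f"chrA{c + 1}"] = 0

    for g in range(params.n_genes):
        chrom = f"chrA{chrom_of_gene[g] + 1}"
        parts, pos = genome[chrom], lengths[chrom]
        spacer = int(struct_rng.integers(*params.intergenic_len, endpoint=True))
        parts.append(_rand_seq(seq_rng, spacer))
        pos += spacer

        n_int = int(struct_rng.integers(*params.introns_per_gene, endpoint=True))
        strand = "-" if struct_rng.random() < params.minus_strand_fraction else "+"
        exon_lens = struct_rng.integers(*params.exon_len, endpoint=True, size=n_int + 1)
        intron_lens = struct_rng.integers(*params.intron_len, endpoint=True, size=n_int)

        exons: list[tuple[int, int]] = []
        for k in range(n_int + 1):
            e_len = int(exon_lens[k])
            exons.append((pos, pos + e_len))
            parts.append(_rand_seq(seq_rng, e_len))
            pos += e_len
            if k < n_int:
                i_len = int(intron_lens[k])
                interior = _rand_seq(seq_rng, i_len - 4)
                # genomic slice of a canonical intron: GT..AG on '+',
                # CT..AC on '-' (reads GT..AG after reverse complement)
                intron_seq = ("GT" + interior + "AG") if strand == "+" else (
                    "CT" + interior + "AC"
                )
                parts.append(intron_seq)
                pos += i_len

        gene_id = f"gene{g:04d}"
        full = Transcript(
            transcript_id=f"{gene_id}.A1",
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
            cds_start=exons[0][0],
            cds_end=exons[-1][1],
        )
        transcripts.append(full)
        canonical.append(full)
        if n_int >= 2 and struct_rng.random() < params.extra_isoform_prob:
            k = int(struct_rng.integers(1, n_int))  # keep exons[0..k]
            sub = exons[: k + 1]
            transcripts.append(
                Transcript(
                    transcript_id=f"{gene_id}.A2",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(sub),
                    cds_start=sub[0][0],
                    cds_end=sub[-1][1],
                )
            )
        lengths[chrom] = pos

    for c in range(params.n_chroms):
        chrom = f"chrA{c + 1}"
        tail = int(struct_rng.integers(*params.intergenic_len, endpoint=True))
        genome[chrom].append(_rand_seq(seq_rng, tail))

    return Ancestor(
        genome={c: "".join(p) for c, p in genome.items()},
        transcripts=transcripts,
        canonical=canonical,
        params=params,
    )


def _genomic_gap(t: Transcript, intron_index: int) -> tuple[int, int, int]:
    """(gap position j, start, end) of a transcription-order intron index."""
    introns = extract_introns(t)
    if not 0 <= intron_index < len(introns):
        raise ValueError(
            f"gene {t.gene_id}: intron index {intron_index} out of range"
        )
    intr = introns[intron_index]
    j = intron_index if t.strand == "+" else t.n_introns - 1 - intron_index
    return j, intr.start, intr.end


def _check_plant_feasible(t: Transcript, j: int, ds: int, de: int) -> None:
    up_len = t.exons[j][1] - t.exons[j][0]
    down_len = t.exons[j + 1][1] - t.exons[j + 1][0]
    need = max(abs(ds), abs(de)) + 2
    if up_len <= need or down_len <= need:
        raise ValueError(
            f"gene {t.gene_id}: flanking exon too short for a {max(abs(ds), abs(de))} bp shift"
        )
    s, e = t.exons[j][1], t.exons[j + 1][0]
    if (e + de) - (s + ds) < 5:
        raise ValueError(f"gene {t.gene_id}: planted shift collapses the intron")


def _plant_site_edits(
    seq: bytearray, strand: str, new_start: int, new_end: int
) -> None:
    """≤4 point edits making the relocated boundaries canonical GT–AG."""
    donor, acceptor = (b"GT", b"AG") if strand == "+" else (b"CT", b"AC")
    seq[new_start : new_start + 2] = donor
    seq[new_end - 2 : new_end] = acceptor


def derive_genome_b(ancestor: Ancestor, params: SimParams | None = None) -> SyntheticDataset:
    """Derive genome B, its annotation, an exact AXT alignment and the truth ledger."""
    params = params or ancestor.params
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    _, _, mut_rng, indel_rng, align_rng, tsl_rng = [
        np.random.default_rng(s) for s in ss.spawn(6)
    ]

    # planted boundary moves, keyed by gene index
    plants: dict[int, tuple[int, int, int, str, str]] = {}
    for g, i, d, mech in params.planted_slidings:
        plants[g] = (i, d, d, mech, "SLIDING")
    for g, i, ds, de in params.planted_nonequal:
        plants[g] = (i, ds, de, "mutation", "NONEQUAL")

    # per-chromosome working copies in A's coordinate frame
    seq_b0 = {c: bytearray(s, "ascii") for c, s in ancestor.genome.items()}

    moves: dict[int, tuple[Transcript, int, int, int, int, str, str]] = {}
    for g, (i, ds, de, mech, kind) in sorted(plants.items()):
        t = ancestor.canonical[g]
        j, s, e = _genomic_gap(t, i)
        _check_plant_feasible(t, j, ds, de)
        seq = seq_b0[t.chrom]
        if mech == "cut_paste":
            d = ds
            src = bytes(seq[min(s, s + d) : max(e, e + d)])
            if d > 0:
                moved = src[e - s : e - s + d] + src[: e - s]
            else:
                moved = src[-d:] + src[: -d]
            seq[min(s, s + d) : max(e, e + d)] = moved
        else:
            _plant_site_edits(seq, t.strand, s + ds, e + de)
        moves[g] = (t, i, j, ds, de, mech, kind)

    # substitution protection: boundary neighbourhoods plus planted gene bodies
    protected = {c: np.zeros(len(s), dtype=bool) for c, s in ancestor.genome.items()}
    pad = 8
    for t in ancestor.canonical:
        mask = protected[t.chrom]
        for intr in extract_introns(t):
            for x in (intr.start, intr.end):
                mask[max(0, x - pad) : min(len(mask), x + pad)] = True
    for g, (t, i, j, ds, de, mech, kind) in moves.items():
        lo, hi = t.span
        protected[t.chrom][max(0, lo - 2) : min(len(protected[t.chrom]), hi + 2)] = True
        _, s, e = _genomic_gap(t, i)
        # keep the relocated boundaries' dinucleotides too (redundant with
        # the gene-body mask, but explicit)
        for x in (s + ds, e + de):
            protected[t.chrom][max(0, x - 2) : x + 2] = True

    # substitutions
    for chrom, seq in seq_b0.items():
        r = mut_rng.random(len(seq))
        hit = np.flatnonzero((r < params.substitution_rate) & ~protected[chrom])
        for pos in hit:
            old = seq[pos : pos + 1]
            choices = [b for b in (b"A", b"C", b"G", b"T") if b != bytes(old)]
            seq[pos : pos + 1] = choices[int(mut_rng.integers(3))]

    # intergenic indels (genic ones only on request, outside protected sites)
    gene_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in ancestor.genome}
    for t in ancestor.transcripts:
        lo, hi = t.span
        gene_spans[t.chrom].append((lo - 20, hi + 20))
    edits: dict[str, list[tuple[int, str, int, str]]] = {c: [] for c in ancestor.genome}
    for chrom, seq in seq_b0.items():
        L = len(seq)
        genic = np.zeros(L, dtype=bool)
        for lo, hi in gene_spans[chrom]:
            genic[max(0, lo) : min(L, hi)] = True
        allowed = ~protected[chrom] if params.genic_indels else ~genic
        cand = np.flatnonzero((indel_rng.random(L) < params.indel_rate) & allowed)
        last_end = -10
        for pos in cand:
            if pos < last_end + 2:
                continue
            size = int(indel_rng.integers(*params.indel_len, endpoint=True))
            if indel_rng.random() < 0.5:
                ins = _rand_seq(indel_rng, size)
                edits[chrom].append((int(pos), "ins", size, ins))
                last_end = int(pos)
            else:
                end = int(pos) + size
                if end >= L or not allowed[pos:end].all():
                    continue
                edits[chrom].append((int(pos), "del", size, ""))
                last_end = end

    # alignment operations per chromosome: M(a_lo, a_hi) / I(seq) / D(a_lo, a_hi)
    ops: dict[str, list[tuple]] = {}
    for chrom, seq in seq_b0.items():
        L = len(seq)
        chrom_ops: list[tuple] = []
        cur = 0
        for pos, kind, size, ins in sorted(edits[chrom]):
            if pos > cur:
                chrom_ops.append(("M", cur, pos))
            if kind == "ins":
                chrom_ops.append(("I", ins))
                cur = pos
            else:
                chrom_ops.append(("D", pos, pos + size))
                cur = pos + size
        if cur < L:
            chrom_ops.append(("M", cur, L))
        ops[chrom] = chrom_ops

    # coordinate liftover A → B from the indel list
    lift_tab: dict[str, tuple[list[int], list[int]]] = {}
    for chrom in seq_b0:
        positions, offsets = [0], [0]
        off = 0
        for pos, kind, size, _ in sorted(edits[chrom]):
            if kind == "ins":
                off += size
                positions.append(pos)
            else:
                off -= size
                positions.append(pos + size)
            offsets.append(off)
        lift_tab[chrom] = (positions, offsets)

    def lift(chrom: str, a: int) -> int:
        import bisect as _b

        positions, offsets = lift_tab[chrom]
        k = _b.bisect_right(positions, a) - 1
        return a + offsets[k]

    # genome B sequences
    genome_b: dict[str, str] = {}
    for chrom, chrom_ops in ops.items():
        src = seq_b0[chrom]
        parts = []
        for op in chrom_ops:
            if op[0] == "M":
                parts.append(src[op[1] : op[2]].decode())
            elif op[0] == "I":
                parts.append(op[1])
        genome_b[_b_chrom(chrom)] = "".join(parts)

    # genome B annotation: lift coordinates, then apply planted moves to
    # every isoform sharing the planted gap
    shifted_gaps: dict[str, dict[tuple[int, int], tuple[int, int]]] = {}
    for g, (t, i, j, ds, de, mech, kind) in moves.items():
        _, s, e = _genomic_gap(t, i)
        shifted_gaps.setdefault(t.gene_id, {})[(s, e)] = (ds, de)

    transcripts_b: list[Transcript] = []
    b_id_of: dict[str, str] = {}
    for t in ancestor.transcripts:
        gaps = shifted_gaps.get(t.gene_id, {})
        new_exons: list[list[int]] = [
            [lift(t.chrom, s), lift(t.chrom, e)] for s, e in t.exons
        ]
        for j in range(len(t.exons) - 1):
            gap = (t.exons[j][1], t.exons[j + 1][0])
            if gap in gaps:
                ds, de = gaps[gap]
                new_exons[j][1] += ds
                new_exons[j + 1][0] += de
        b_id = t.transcript_id.replace(".A", ".B")
        b_id_of[t.transcript_id] = b_id
        exons = tuple((s, e) for s, e in new_exons)
        transcripts_b.append(
            Transcript(
                transcript_id=b_id,
                gene_id=t.gene_id,
                chrom=_b_chrom(t.chrom),
                strand=t.strand,
                exons=exons,
                cds_start=exons[0][0],
                cds_end=exons[-1][1],
            )
        )

    # unaligned windows: exclude a ±2 bp window around the genomically first
    # intron start of some genes without planted events
    n_unaligned = int(round(params.unaligned_fraction * params.n_genes))
    eligible = [
        g
        for g in range(params.n_genes)
        if g not in moves and ancestor.canonical[g].n_introns > 0
    ]
    windows: dict[str, list[tuple[int, int]]] = {c: [] for c in ancestor.genome}
    expected_skipped = 0
    if n_unaligned > 0 and eligible:
        chosen = align_rng.choice(
            eligible, size=min(n_unaligned, len(eligible)), replace=False
        )
        for g in sorted(int(x) for x in chosen):
            t = ancestor.canonical[g]
            s = t.exons[0][1]  # first genomic gap start
            windows[t.chrom].append((s - 2, s + 3))
            expected_skipped += 1
    for chrom in windows:
        windows[chrom].sort()

    # AXT records from the edit history, split at unaligned windows
    axt_records: list[AxtRecord] = []
    order = 0
    for chrom in sorted(ops):
        a_seq_full = ancestor.genome[chrom]
        b_src = seq_b0[chrom]
        win = windows[chrom]

        a_parts: list[str] = []
        b_parts: list[str] = []
        rec_a_start = rec_b_start = None
        a_cur = b_cur = 0

        def flush(a_end: int, b_end: int) -> None:
            nonlocal rec_a_start, rec_b_start, order
            if rec_a_start is None:
                return
            a_row = "".join(a_parts)
            b_row = "".join(b_parts)
            n_match = sum(
                1 for x, y in zip(a_row, b_row) if x != "-" and y != "-" and x == y
            )
            axt_records.append(
                AxtRecord(
                    index=order,
                    a_chrom=chrom,
                    a_start=rec_a_start,
                    a_end=a_end,
                    b_chrom=_b_chrom(chrom),
                    b_start=rec_b_start,
                    b_end=b_end,
                    strand="+",
                    score=100 * n_match,
                    a_seq=a_row,
                    b_seq=b_row,
                    order=order,
                )
            )
            order += 1
            a_parts.clear()
            b_parts.clear()
            rec_a_start = rec_b_start = None

        def excluded_runs(lo: int, hi: int) -> list[tuple[int, int, bool]]:
            """Split [lo, hi) into (sub_lo, sub_hi, excluded) runs."""
            runs = []
            cur = lo
            for wlo, whi in win:
                if whi <= lo or wlo >= hi:
                    continue
                wlo, whi = max(wlo, lo), min(whi, hi)
                if wlo > cur:
                    runs.append((cur, wlo, False))
                runs.append((wlo, whi, True))
                cur = whi
            if cur < hi:
                runs.append((cur, hi, False))
            return runs

        for op in ops[chrom]:
            if op[0] == "M":
                for lo, hi, excl in excluded_runs(op[1], op[2]):
                    n = hi - lo
                    if excl:
                        flush(a_cur, b_cur)
                        a_cur += n
                        b_cur += n
                    else:
                        if rec_a_start is None:
                            rec_a_start, rec_b_start = a_cur, b_cur
                        a_parts.append(a_seq_full[lo:hi])
                        b_parts.append(b_src[lo:hi].decode())
                        a_cur += n
                        b_cur += n
            elif op[0] == "I":
                if rec_a_start is not None:
                    a_parts.append("-" * len(op[1]))
                    b_parts.append(op[1])
                b_cur += len(op[1])
            else:  # D
                n = op[2] - op[1]
                if rec_a_start is not None:
                    a_parts.append(a_seq_full[op[1] : op[2]])
                    b_parts.append("-" * n)
                a_cur += n
        flush(a_cur, b_cur)

    # TSL labels for genome-A transcripts
    tsl: dict[str, str] = {}
    planted_tids = {moves[g][0].transcript_id for g in moves}
    for t in ancestor.transcripts:
        if t.transcript_id in planted_tids:
            tsl[t.transcript_id] = "5" if params.planted_low_tsl else "1"
        elif (
            t.gene_id not in shifted_gaps
            and params.decoy_tsl_fraction > 0
            and tsl_rng.random() < params.decoy_tsl_fraction
        ):
            tsl[t.transcript_id] = str(tsl_rng.choice(["4", "5", "NA"]))
        else:
            tsl[t.transcript_id] = "1"

    # truth ledger
    b_by_id = {t.transcript_id: t for t in transcripts_b}
    truth: list[TruthRecord] = []
    for g in sorted(moves):
        t, i, j, ds, de, mech, kind = moves[g]
        tb = b_by_id[b_id_of[t.transcript_id]]
        a_int = extract_introns(t)[i]
        b_int = extract_introns(tb)[i]
        a_sites = splice_dinucleotides(ancestor.genome, a_int)
        b_sites = splice_dinucleotides(genome_b, b_int)
        truth.append(
            TruthRecord(
                gene_id=t.gene_id,
                a_transcript=t.transcript_id,
                b_transcript=tb.transcript_id,
                chrom_a=t.chrom,
                intron_index=i,
                kind=kind,
                delta_start=ds,
                delta_end=de,
                mechanism=mech,
                a_donor=a_sites.donor,
                a_acceptor=a_sites.acceptor,
                b_donor=b_sites.donor,
                b_acceptor=b_sites.acceptor,
                a_phase=intron_phase(t, i),
                b_phase=intron_phase(tb, i),
            )
        )

    return SyntheticDataset(
        genome_a=dict(ancestor.genome),
        genome_b=genome_b,
        transcripts_a=list(ancestor.transcripts),
        transcripts_b=transcripts_b,
        axt_records=axt_records,
        tsl=tsl,
        truth=truth,
        expected_skipped=expected_skipped,
        params=params,
    )


def generate_dataset(params: SimParams) -> SyntheticDataset:
    """Convenience: ancestor plus derived genome B in one call."""
    return derive_genome_b(generate_ancestor(params), params)


def plan_plantings(
    ancestor: Ancestor,
    n_sliding: int,
    n_nonequal: int,
    rng: np.random.Generator,
    shift_lengths: Sequence[int] = (1, 2, 3, 4, 5),
    mechanisms: Sequence[str] = ("mutation", "cut_paste"),
    plus_strand_only: bool = False,
) -> tuple[list[tuple[int, int, int, str]], list[tuple[int, int, int, int]]]:
    """Choose feasible planting targets on distinct genes of an ancestor.

    Returns ``(planted_slidings, planted_nonequal)`` suitable for
    :class:`SimParams`.  Shift signs are drawn at random; non-equal
    deltas are unequal pairs in ``[-3, 3]``, roughly half of them with a
    net change divisible by three.
    """
    need = max(max(abs(d) for d in shift_lengths), 3) + 3
    eligible = []
    for g, t in enumerate(ancestor.canonical):
        if plus_strand_only and t.strand != "+":
            continue
        for i in range(t.n_introns):
            j = i if t.strand == "+" else t.n_introns - 1 - i
            up = t.exons[j][1] - t.exons[j][0]
            down = t.exons[j + 1][1] - t.exons[j + 1][0]
            if up > need and down > need:
                eligible.append((g, i))
                break
    rng.shuffle(eligible)
    if len(eligible) < n_sliding + n_nonequal:
        raise ValueError(
            f"only {len(eligible)} genes eligible for planting, "
            f"need {n_sliding + n_nonequal}"
        )
    slidings = []
    for k in range(n_sliding):
        g, i = eligible[k]
        d = int(rng.choice(shift_lengths)) * (1 if rng.random() < 0.5 else -1)
        mech = str(rng.choice(mechanisms))
        slidings.append((g, i, d, mech))
    nonequal = []
    pairs = [(ds, de) for ds in range(-3, 4) for de in range(-3, 4) if ds != de]
    frame_ok = [p for p in pairs if (p[0] - p[1]) % 3 == 0]
    frame_bad = [p for p in pairs if (p[0] - p[1]) % 3 != 0]
    for k in range(n_nonequal):
        g, i = eligible[n_sliding + k]
        pool = frame_ok if k % 2 == 0 else frame_bad
        ds, de = pool[int(rng.integers(len(pool)))]
        nonequal.append((g, i, ds, de))
    return slidings, nonequal


def emit_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as the plain-text files the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_a": out / "genome_a.fa",
        "genome_b": out / "genome_b.fa",
        "annotation_a": out / "annotation_a.genePred",
        "annotation_b": out / "annotation_b.genePred",
        "alignment": out / "alignment.axt",
        "tsl": out / "tsl.tsv",
        "truth": out / "truth.tsv",
        "params": out / "params.json",
    }
    write_fasta(ds.genome_a, str(paths["genome_a"]))
    write_fasta(ds.genome_b, str(paths["genome_b"]))
    with open(paths["annotation_a"], "w") as fh:
        write_genepred(ds.transcripts_a, fh)
    with open(paths["annotation_b"], "w") as fh:
        write_genepred(ds.transcripts_b, fh)
    with open(paths["alignment"], "w") as fh:
        write_axt(ds.axt_records, fh)
    with open(paths["tsl"], "w") as fh:
        fh.write("transcript_id\ttsl\n")
        for tid in sorted(ds.tsl):
            fh.write(f"{tid}\t{ds.tsl[tid]}\n")
    cols = [
        "gene_id", "a_transcript", "b_transcript", "chrom_a", "intron_index",
        "kind", "delta_start", "delta_end", "mechanism", "a_donor",
        "a_acceptor", "b_donor", "b_acceptor", "a_phase", "b_phase",
    ]
    with open(paths["truth"], "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in ds.truth:
            d = asdict(rec)
            fh.write(
                "\t".join("" if d[c] is None else str(d[c]) for c in cols) + "\n"
            )
    if ds.params is not None:
        with open(paths["params"], "w") as fh:
            json.dump(asdict(ds.params), fh, indent=1, default=str)
            fh.write("\n")
    return paths


def read_truth(path: str | Path) -> list[TruthRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            records.append(
                TruthRecord(
                    gene_id=row["gene_id"],
                    a_transcript=row["a_transcript"],
                    b_transcript=row["b_transcript"],
                    chrom_a=row["chrom_a"],
                    intron_index=int(row["intron_index"]),
                    kind=row["kind"],
                    delta_start=int(row["delta_start"]),
                    delta_end=int(row["delta_end"]),
                    mechanism=row["mechanism"],
                    a_donor=row["a_donor"],
                    a_acceptor=row["a_acceptor"],
                    b_donor=row["b_donor"],
                    b_acceptor=row["b_acceptor"],
                    a_phase=int(row["a_phase"]) if row["a_phase"] else None,
                    b_phase=int(row["b_phase"]) if row["b_phase"] else None,
                )
            )
    return records


def build_coordinate_example() -> tuple[list[Intron], list[Intron], BlockMap]:
    """The classic hypothetical coordinate change: an intron at (100, 500)
    whose boundaries both move to (101, 501) — a 1 bp slide — encoded as
    two single-intron annotations over an identity alignment."""
    a = Intron("txA", 0, "chrA1", "+", 100, 500)
    b = Intron("txB", 0, "chrB1", "+", 101, 501)
    block = AlignmentBlock(
        a_chrom="chrA1", a_start=0, b_chrom="chrB1", b_start=0, length=600
    )
    return [a], [b], BlockMap([block])


def build_background_example() -> SyntheticDataset:
    """Executable form of the worked sequence example.

    Genome A carries GAC|gtcct…tgag|CTAA and genome B the cut-and-paste
    result GACC|gtcct…tgag|TAA, with the elided intron interior replaced
    by :data:`BACKGROUND_SPACER`.  The intron sequence is identical in
    both genomes; only the exon bases around it moved, a +1 bp slide.
    """
    intron = "gtcct" + BACKGROUND_SPACER + "tgag"
    seq_a = ("GAC" + intron + "CTAA").upper()
    seq_b = ("GACC" + intron + "TAA").upper()
    L = len(seq_a)  # 36; same in B (cut-and-paste preserves length)
    ta = Transcript(
        "bgA.A1", "bgA", "chrA1", "+",
        exons=((0, 3), (3 + len(intron), L)), cds_start=0, cds_end=L,
    )
    tb = Transcript(
        "bgA.B1", "bgA", "chrB1", "+",
        exons=((0, 4), (4 + len(intron), L)), cds_start=0, cds_end=L,
    )
    rec = AxtRecord(
        index=0, a_chrom="chrA1", a_start=0, a_end=L,
        b_chrom="chrB1", b_start=0, b_end=L,
        strand="+", score=100 * L, a_seq=seq_a, b_seq=seq_b, order=0,
    )
    a_sites = splice_dinucleotides({"chrA1": seq_a}, extract_introns(ta)[0])
    b_sites = splice_dinucleotides({"chrB1": seq_b}, extract_introns(tb)[0])
    truth = [
        TruthRecord(
            gene_id="bgA", a_transcript="bgA.A1", b_transcript="bgA.B1",
            chrom_a="chrA1", intron_index=0, kind="SLIDING",
            delta_start=1, delta_end=1, mechanism="cut_paste",
            a_donor=a_sites.donor, a_acceptor=a_sites.acceptor,
            b_donor=b_sites.donor, b_acceptor=b_sites.acceptor,
            a_phase=intron_phase(ta, 0), b_phase=intron_phase(tb, 0),
        )
    ]
    return SyntheticDataset(
        genome_a={"chrA1": seq_a},
        genome_b={"chrB1": seq_b},
        transcripts_a=[ta],
        transcripts_b=[tb],
        axt_records=[rec],
        tsl={"bgA.A1": "1"},
        truth=truth,
        expected_skipped=0,
        params=None,
    )
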
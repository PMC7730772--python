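"""Intron matching, shift classification, annotation and deduplication.

The detector projects both borders of every reference (genome A) intron
through the alignment and compares them with annotated introns of the
other genome (B).  With ``delta = b − projected a`` for each border,
expressed in A's reading direction:

* ``delta_start == delta_end == 0``                      → CONSERVED
* ``delta_start == delta_end`` and ``1 ≤ |delta| ≤ 5``   → SLIDING
  (both borders moved the same distance in the same direction; intron
  length is unchanged)
* unequal deltas, both within the bound                  → NONEQUAL
  (intron length changed; the net exon-length change
  ``delta_start − delta_end`` preserves reading frame iff it is a
  multiple of three)

The 5 bp default bound reflects that boundary relocations much longer
than this are better explained as intron loss plus gain.  Introns whose
borders fall outside every aligned block are skipped and counted, not
errors: pairwise genome alignments only cover conserved regions.

Rather than projecting the exclusive end coordinate (which is UNMAPPED
at a block's edge by convention), the detector projects the first and
last intronic bases and rebuilds half-open borders from them.

When the aligned B locus lies on B's minus strand, border types are
reconciled through the orientation flip — an A start border corresponds
to a B end border — and delta signs are still reported in A's reading
direction, so "equal shift in the same direction" keeps one meaning
under inversion.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .alignment_projection import UNMAPPED, BlockMap
from .gene_models import (
    Intron,
    SpliceSites,
    Transcript,
    intron_phase,
    splice_dinucleotides,
)

__all__ = [
    "DEFAULT_MAX_SHIFT",
    "BorderComparison",
    "ShiftEvent",
    "MatchResult",
    "DedupGroup",
    "match_intron_pairs",
    "classify_shift",
    "annotate_event",
    "detect_events",
    "deduplicate",
]

DEFAULT_MAX_SHIFT = 5  # bp; boundary shifts beyond this are not called events


@dataclass(frozen=True)
class BorderComparison:
    """A matched A/B intron pair with per-border offsets.

    ``delta_start``/``delta_end`` are ``b − projected a`` for the
    same-type border, in A's reading direction.  ``b_orientation`` is
    the alignment strand of the B locus ('-' means the locus is
    inverted and border types were flipped before comparison).
    """

    a_intron: Intron
    b_intron: Intron
    delta_start: int
    delta_end: int
    b_orientation: str = "+"


@dataclass(frozen=True)
class ShiftEvent:
    """A classified intron-boundary comparison with its annotations."""

    comparison: BorderComparison
    kind: str  # CONSERVED | SLIDING | NONEQUAL
    shift_length: int | None  # |delta|, SLIDING only
    net_exon_change: int  # delta_start − delta_end
    frame_preserving: bool | None  # NONEQUAL only: net change divisible by 3
    one_sided: bool = False  # NONEQUAL with exactly one border moved
    a_sites: SpliceSites | None = None
    b_sites: SpliceSites | None = None
    sites_preserved: bool | None = None
    a_phase: int | None = None
    b_phase: int | None = None
    a_gene_id: str | None = None
    b_gene_id: str | None = None
    tsl: str | None = None
    dedup_group: str | None = None
    dedup_size: int = 1
    dedup_representative: bool = True
    evidence: str = ""  # free-text transcriptome-evidence column, user-filled

    @property
    def a_transcript(self) -> str:
        return self.comparison.a_intron.transcript_id

    @property
    def b_transcript(self) -> str:
        return self.comparison.b_intron.transcript_id


@dataclass
class MatchResult:
    comparisons: list[BorderComparison]
    n_skipped: int = 0  # A introns with an unmapped border
    n_unpaired: int = 0  # both borders mapped but no B intron within bound
    discarded: list[BorderComparison] = field(default_factory=list)


def match_intron_pairs(
    a_introns: Sequence[Intron],
    b_introns: Sequence[Intron],
    bmap: BlockMap,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> MatchResult:
    """Pair A introns with B introns via projected borders.

    For each A intron with both borders inside aligned blocks, B introns
    on the projected chromosome whose same-type borders both lie within
    ``max_shift`` of the projections are candidates; the one minimising
    ``|delta_start| + |delta_end|`` is kept (ties: smaller B start).
    Competing candidates are logged in ``discarded``.  A introns with
    any unmapped border are skipped and counted.
    """
    if max_shift < 1:
        raise ValueError("max_shift must be ≥ 1")
    by_chrom: dict[str, list[Intron]] = defaultdict(list)
    for b in b_introns:
        by_chrom[b.chrom].append(b)
    starts_index: dict[str, tuple[list[int], list[Intron]]] = {}
    for chrom, introns in by_chrom.items():
        introns.sort(key=lambda i: (i.start, i.end, i.transcript_id, i.index))
        starts_index[chrom] = ([i.start for i in introns], introns)

    result = MatchResult(comparisons=[])
    ordered_a = sorted(
        a_introns, key=lambda i: (i.chrom, i.start, i.end, i.transcript_id, i.index)
    )
    for a in ordered_a:
        p_first = bmap.project_full(a.chrom, a.start)  # first intronic base
        p_last = bmap.project_full(a.chrom, a.end - 1)  # last intronic base
        if (
            p_first is UNMAPPED
            or p_last is UNMAPPED
            or p_first.b_chrom != p_last.b_chrom
            or p_first.b_strand != p_last.b_strand
        ):
            result.n_skipped += 1
            continue
        orientation = p_first.b_strand
        if orientation == "+":
            pred_start, pred_end = p_first.b_coord, p_last.b_coord + 1
        else:
            pred_start, pred_end = p_last.b_coord, p_first.b_coord + 1
        if pred_end <= pred_start:
            result.n_skipped += 1
            continue

        index = starts_index.get(p_first.b_chrom)
        candidates: list[BorderComparison] = []
        if index is not None:
            starts, introns = index
            lo = bisect.bisect_left(starts, pred_start - max_shift)
            hi = bisect.bisect_right(starts, pred_start + max_shift)
            for b in introns[lo:hi]:
                if orientation == "+":
                    ds = b.start - pred_start
                    de = b.end - pred_end
                else:
                    # A start border ↔ B end border under the inversion;
                    # signs expressed in A's reading direction.
                    ds = pred_end - b.end
                    de = pred_start - b.start
                if abs(ds) <= max_shift and abs(de) <= max_shift:
                    candidates.append(
                        BorderComparison(a, b, ds, de, b_orientation=orientation)
                    )
        if not candidates:
            result.n_unpaired += 1
            continue
        candidates.sort(
            key=lambda c: (
                abs(c.delta_start) + abs(c.delta_end),
                c.b_intron.start,
                c.b_intron.transcript_id,
            )
        )
        result.comparisons.append(candidates[0])
        result.discarded.extend(candidates[1:])
    return result


def classify_shift(
    c: BorderComparison, max_shift: int = DEFAULT_MAX_SHIFT
) -> ShiftEvent:
    """Classify one border comparison as CONSERVED, SLIDING or NONEQUAL."""
    ds, de = c.delta_start, c.delta_end
    if abs(ds) > max_shift or abs(de) > max_shift:
        raise ValueError("deltas beyond max_shift must be rejected at match time")
    net = ds - de
    if ds == 0 and de == 0:
        return ShiftEvent(c, "CONSERVED", None, 0, None)
    if ds == de:
        return ShiftEvent(c, "SLIDING", abs(ds), 0, None)
    return ShiftEvent(
        c,
        "NONEQUAL",
        None,
        net,
        frame_preserving=(net % 3 == 0),
        one_sided=(ds == 0) != (de == 0),
    )


def annotate_event(
    event: ShiftEvent,
    genome_a: Mapping[str, str] | None,
    genome_b: Mapping[str, str] | None,
    transcripts_a: Mapping[str, Transcript],
    transcripts_b: Mapping[str, Transcript],
) -> ShiftEvent:
    """Attach splice sites, phases and gene ids to an event.

    Missing sequence leaves the site fields unset; the event is retained
    rather than dropped.
    """
    a_int, b_int = event.comparison.a_intron, event.comparison.b_intron
    a_sites = b_sites = None
    if genome_a is not None:
        try:
            a_sites = splice_dinucleotides(genome_a, a_int)
        except (KeyError, ValueError):
            a_sites = None
    if genome_b is not None:
        try:
            b_sites = splice_dinucleotides(genome_b, b_int)
        except (KeyError, ValueError):
            b_sites = None
    preserved = None
    if a_sites is not None and b_sites is not None:
        preserved = (
            a_sites.donor == b_sites.donor and a_sites.acceptor == b_sites.acceptor
        )
    ta = transcripts_a.get(a_int.transcript_id)
    tb = transcripts_b.get(b_int.transcript_id)
    a_phase = intron_phase(ta, a_int.index) if ta is not None else None
    b_phase = intron_phase(tb, b_int.index) if tb is not None else None
    return replace(
        event,
        a_sites=a_sites,
        b_sites=b_sites,
        sites_preserved=preserved,
        a_phase=a_phase,
        b_phase=b_phase,
        a_gene_id=ta.gene_id if ta is not None else None,
        b_gene_id=tb.gene_id if tb is not None else None,
    )


def detect_events(
    a_introns: Sequence[Intron],
    b_introns: Sequence[Intron],
    bmap: BlockMap,
    transcripts_a: Mapping[str, Transcript],
    transcripts_b: Mapping[str, Transcript],
    genome_a: Mapping[str, str] | None = None,
    genome_b: Mapping[str, str] | None = None,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> tuple[list[ShiftEvent], MatchResult]:
    """Match, classify and annotate in one pass; returns all events
    (including CONSERVED) plus matching statistics."""
    match = match_intron_pairs(a_introns, b_introns, bmap, max_shift=max_shift)
    events = [
        annotate_event(
            classify_shift(c, max_shift=max_shift),
            genome_a,
            genome_b,
            transcripts_a,
            transcripts_b,
        )
        for c in match.comparisons
    ]
    return events, match


@dataclass
class DedupGroup:
    group_id: str
    representative: ShiftEvent
    members: list[ShiftEvent]

    @property
    def size(self) -> int:
        return len(self.members)


def _flank_signature(
    event: ShiftEvent, genome_a: Mapping[str, str], flank: int
) -> tuple | None:
    a = event.comparison.a_intron
    seq = genome_a.get(a.chrom)
    if seq is None or a.start - flank < 0 or a.end + flank > len(seq):
        return None
    return (
        str(seq[a.start - flank : a.start]).upper(),
        str(seq[a.end : a.end + flank]).upper(),
        a.length,
        event.comparison.delta_start,
        event.comparison.delta_end,
    )


def deduplicate(
    events: Sequence[ShiftEvent],
    flank: int = 20,
    genome_a: Mapping[str, str] | None = None,
) -> list[DedupGroup]:
    """Collapse repeated observations of one boundary change.

    Events are grouped when they share (i) the same A gene, intron index
    and delta signature — the same A intron re-detected against several
    partner contexts — or (ii) identical A-side intron flanks of length
    ``flank`` on both sides with the same delta signature, which
    collapses matching transcripts annotated on alternative loci or
    patches.  Rule (ii) needs ``genome_a``.  Each group carries a
    deterministic id, a representative (first member under the output
    sort) and its member count.
    """
    if flank < 0:
        raise ValueError("flank must be ≥ 0")
    ordered = sorted(
        events,
        key=lambda e: (
            e.a_gene_id or "",
            e.a_transcript,
            e.comparison.a_intron.chrom,
            e.comparison.a_intron.start,
            e.b_transcript,
            e.comparison.b_intron.start,
        ),
    )
    parent = list(range(len(ordered)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    keyed: dict[tuple, int] = {}
    for i, e in enumerate(ordered):
        key1 = (
            "gene",
            e.a_gene_id or e.a_transcript,
            e.comparison.a_intron.index,
            e.comparison.delta_start,
            e.comparison.delta_end,
        )
        keys = [key1]
        if genome_a is not None:
            sig = _flank_signature(e, genome_a, flank)
            if sig is not None:
                keys.append(("flank", *sig))
        for key in keys:
            if key in keyed:
                union(i, keyed[key])
            else:
                keyed[key] = i

    members: dict[int, list[ShiftEvent]] = defaultdict(list)
    for i, e in enumerate(ordered):
        members[find(i)].append(e)
    groups: list[DedupGroup] = []
    for n, root in enumerate(sorted(members), start=1):
        group_id = f"g{n:04d}"
        evs = [
            replace(
                e,
                dedup_group=group_id,
                dedup_size=len(members[root]),
                dedup_representative=(k == 0),
            )
            for k, e in enumerate(members[root])
        ]
        groups.append(DedupGroup(group_id, evs[0], evs))
    return groups
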
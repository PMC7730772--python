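"""Transcript-Support-Level filtering, summaries, reports and the pipeline.

TSL is the GENCODE label grading experimental support for a transcript
model: TSL1 means every splice junction is supported, TSL4/TSL5/TSLNA
mark predicted transcripts with no experimental support.  Events called
on predicted reference transcripts are dropped (default cutoff: keep
TSL ≤ 3; transcripts absent from the table count as NA).  Filtering is
applied to the reference (A) side only.

Outputs are two TSV event tables — one for equal (sliding) shifts, one
for non-equal shifts — plus a human-readable summary and a key=value
run log.  Row order is fixed (gene id, then A intron start) so a rerun
with identical inputs is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .alignment_projection import BlockMap, parse_axt
from .event_detection import (
    DEFAULT_MAX_SHIFT,
    DedupGroup,
    ShiftEvent,
    deduplicate,
    detect_events,
)
from .gene_models import (
    Intron,
    Transcript,
    canonical_by_gene,
    extract_introns,
    load_fasta,
    parse_genepred,
)

__all__ = [
    "TSL_LABELS",
    "TslParseError",
    "RunConfig",
    "PipelineResult",
    "parse_tsl_table",
    "filter_by_tsl",
    "summarize",
    "write_report",
    "run_pipeline",
]

TSL_LABELS = {"1", "2", "3", "4", "5", "NA"}


class TslParseError(ValueError):
    """Raised on a malformed TSL table row."""


def parse_tsl_table(stream: IO[str] | Iterable[str]) -> dict[str, str]:
    """Parse a two-column ``transcript_id<TAB>tsl`` table.

    Labels may be bare (``1`` … ``5``, ``NA``) or prefixed (``TSL1``,
    ``tslNA``).  A header row naming the columns is skipped.
    """
    table: dict[str, str] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise TslParseError(f"line {lineno}: expected 2 columns, got {len(fields)}")
        tid, label = fields[0].strip(), fields[1].strip().upper()
        if lineno == 1 and label in ("TSL", "LEVEL"):
            continue
        if label.startswith("TSL"):
            label = label[3:]
        if label not in TSL_LABELS:
            raise TslParseError(f"line {lineno}: bad TSL label {fields[1]!r}")
        table[tid] = label
    return table


def filter_by_tsl(
    events: Sequence[ShiftEvent],
    tsl_table: Mapping[str, str],
    cutoff: int | None = 3,
) -> tuple[list[ShiftEvent], list[tuple[ShiftEvent, str]]]:
    """Keep events whose reference transcript has TSL ≤ ``cutoff``.

    ``cutoff=None`` disables the filter.  NA labels and transcripts
    absent from the table never pass an enabled filter (they mark
    predicted transcripts with no experimental support).  Returns
    ``(kept, dropped)`` with a reason string per drop; kept events carry
    their TSL label.
    """
    if cutoff is not None and cutoff not in range(1, 6):
        raise ValueError(f"tsl_cutoff must be in 1..5 or None, got {cutoff}")
    kept: list[ShiftEvent] = []
    dropped: list[tuple[ShiftEvent, str]] = []
    for e in events:
        label = tsl_table.get(e.a_transcript, "NA")
        e = replace(e, tsl=label)
        if cutoff is None:
            kept.append(e)
        elif label == "NA":
            if e.a_transcript in tsl_table:
                dropped.append((e, "predicted transcript (TSLNA)"))
            else:
                dropped.append((e, "transcript absent from TSL table (treated as NA)"))
        elif int(label) <= cutoff:
            kept.append(e)
        else:
            dropped.append((e, f"predicted transcript (TSL{label} > cutoff {cutoff})"))
    return kept, dropped


def summarize(events: Sequence[ShiftEvent], n_skipped: int = 0) -> dict:
    """Count events by kind plus the shift-length histogram and the
    splice-site / frame / uniqueness tallies."""
    sliding = [e for e in events if e.kind == "SLIDING"]
    nonequal = [e for e in events if e.kind == "NONEQUAL"]
    hist: dict[int, int] = {}
    for e in sliding:
        hist[e.shift_length] = hist.get(e.shift_length, 0) + 1
    groups = {e.dedup_group for e in events if e.dedup_group is not None}
    return {
        "n_events": len(events),
        "n_conserved": sum(1 for e in events if e.kind == "CONSERVED"),
        "n_sliding": len(sliding),
        "n_nonequal": len(nonequal),
        "n_one_sided": sum(1 for e in nonequal if e.one_sided),
        "shift_length_hist": dict(sorted(hist.items())),
        "n_sites_preserved_sliding": sum(
            1 for e in sliding if e.sites_preserved is True
        ),
        "n_canonical_both_sliding": sum(
            1
            for e in sliding
            if e.a_sites is not None
            and e.b_sites is not None
            and e.a_sites.canonical
            and e.b_sites.canonical
        ),
        "n_frame_preserving": sum(
            1 for e in nonequal if e.frame_preserving is True
        ),
        "n_unique_groups": len(groups),
        "n_skipped_borders": n_skipped,
    }


_COLUMNS = [
    "gene_id", "a_transcript", "b_transcript", "a_chrom", "a_intron_start",
    "a_intron_end", "b_chrom", "b_intron_start", "b_intron_end",
    "intron_index", "delta_start", "delta_end", "kind", "shift_length",
    "net_exon_change", "a_donor", "a_acceptor", "b_donor", "b_acceptor",
    "a_canonical", "b_canonical", "sites_preserved", "a_phase", "b_phase",
    "frame_preserving", "one_sided", "tsl", "dedup_group", "dedup_size",
    "evidence",
]


def _events_frame(events: Sequence[ShiftEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        a, b = e.comparison.a_intron, e.comparison.b_intron
        rows.append(
            {
                "gene_id": e.a_gene_id or a.transcript_id,
                "a_transcript": a.transcript_id,
                "b_transcript": b.transcript_id,
                "a_chrom": a.chrom,
                "a_intron_start": a.start,
                "a_intron_end": a.end,
                "b_chrom": b.chrom,
                "b_intron_start": b.start,
                "b_intron_end": b.end,
                "intron_index": a.index,
                "delta_start": e.comparison.delta_start,
                "delta_end": e.comparison.delta_end,
                "kind": e.kind,
                "shift_length": e.shift_length,
                "net_exon_change": e.net_exon_change,
                "a_donor": e.a_sites.donor if e.a_sites else None,
                "a_acceptor": e.a_sites.acceptor if e.a_sites else None,
                "b_donor": e.b_sites.donor if e.b_sites else None,
                "b_acceptor": e.b_sites.acceptor if e.b_sites else None,
                "a_canonical": e.a_sites.canonical if e.a_sites else None,
                "b_canonical": e.b_sites.canonical if e.b_sites else None,
                "sites_preserved": e.sites_preserved,
                "a_phase": e.a_phase,
                "b_phase": e.b_phase,
                "frame_preserving": e.frame_preserving,
                "one_sided": e.one_sided,
                "tsl": e.tsl,
                "dedup_group": e.dedup_group,
                "dedup_size": e.dedup_size,
                "evidence": e.evidence,
            }
        )
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return df.sort_values(
        ["gene_id", "a_intron_start", "b_transcript"], kind="mergesort"
    ).reset_index(drop=True)


def write_report(
    events: Sequence[ShiftEvent],
    summary: Mapping,
    out_dir: str | Path,
    config: "RunConfig | None" = None,
) -> dict[str, Path]:
    """Write the sliding/non-equal event tables, summary and run log."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    paths = {
        "sliding": out / "sliding_events.tsv",
        "nonequal": out / "nonequal_events.tsv",
        "summary": out / "summary.txt",
        "run_log": out / "run_log.txt",
    }
    _events_frame([e for e in events if e.kind == "SLIDING"]).to_csv(
        paths["sliding"], sep="\t", index=False
    )
    _events_frame([e for e in events if e.kind == "NONEQUAL"]).to_csv(
        paths["nonequal"], sep="\t", index=False
    )
    with open(paths["summary"], "w") as fh:
        for key, val in summary.items():
            fh.write(f"{key}: {val}\n")
    with open(paths["run_log"], "w") as fh:
        if config is not None:
            for key, val in sorted(vars(config).items()):
                fh.write(f"config.{key}={val}\n")
        for key, val in summary.items():
            fh.write(f"summary.{key}={val}\n")
    return paths


@dataclass
class RunConfig:
    """Resolved inputs and knobs for one detection run."""

    annotation_a: str
    annotation_b: str
    alignment: str
    genome_a: str | None = None
    genome_b: str | None = None
    tsl: str | None = None
    out_dir: str = "intronslide_out"
    max_shift: int = DEFAULT_MAX_SHIFT
    tsl_cutoff: int | None = 3
    dedup_flank: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_shift < 1:
            raise ValueError("max_shift must be ≥ 1")
        if self.tsl_cutoff is not None and self.tsl_cutoff not in range(1, 6):
            raise ValueError("tsl_cutoff must be in 1..5 or None")


@dataclass
class PipelineResult:
    events: list[ShiftEvent]  # annotated, deduplicated, TSL-labelled kept events
    dropped: list[tuple[ShiftEvent, str]]
    conserved: int
    groups: list[DedupGroup]
    summary: dict
    stage_counts: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _load_annotation(path: str) -> list[Transcript]:
    with open(path) as fh:
        return parse_genepred(fh)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full detection pipeline from files to report files.

    Stages: parse annotations → canonical isoform selection → intron
    extraction → alignment block map → border projection and matching →
    shift classification → splice-site/phase annotation → deduplication
    → TSL filter → report.  Counts are logged at every stage.
    """
    stage = "parse annotation A"
    try:
        transcripts_a = _load_annotation(config.annotation_a)
        stage = "parse annotation B"
        transcripts_b = _load_annotation(config.annotation_b)
        stage = "parse alignment"
        with open(config.alignment) as fh:
            records = parse_axt(fh)
        genome_a = load_fasta(config.genome_a) if config.genome_a else None
        genome_b = load_fasta(config.genome_b) if config.genome_b else None
        b_sizes = {c: len(s) for c, s in genome_b.items()} if genome_b else None
        stage = "build block map"
        bmap = BlockMap.from_records(records, b_sizes=b_sizes)
        stage = "detect"
        result = _detect_stage(
            transcripts_a, transcripts_b, bmap, genome_a, genome_b, config
        )
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
    result.paths = write_report(result.events, result.summary, config.out_dir, config)
    return result


def _detect_stage(
    transcripts_a: Sequence[Transcript],
    transcripts_b: Sequence[Transcript],
    bmap: BlockMap,
    genome_a: Mapping[str, str] | None,
    genome_b: Mapping[str, str] | None,
    config: RunConfig,
) -> PipelineResult:
    canon_a = canonical_by_gene(transcripts_a)
    canon_b = canonical_by_gene(transcripts_b)
    a_introns: list[Intron] = [i for t in canon_a for i in extract_introns(t)]
    b_introns: list[Intron] = [i for t in canon_b for i in extract_introns(t)]
    by_id_a = {t.transcript_id: t for t in transcripts_a}
    by_id_b = {t.transcript_id: t for t in transcripts_b}

    events, match = detect_events(
        a_introns,
        b_introns,
        bmap,
        by_id_a,
        by_id_b,
        genome_a=genome_a,
        genome_b=genome_b,
        max_shift=config.max_shift,
    )
    conserved = sum(1 for e in events if e.kind == "CONSERVED")
    shifted = [e for e in events if e.kind != "CONSERVED"]

    groups = deduplicate(shifted, flank=config.dedup_flank, genome_a=genome_a)
    deduped = [e for grp in groups for e in grp.members]

    if config.tsl is not None:
        with open(config.tsl) as fh:
            tsl_table = parse_tsl_table(fh)
        kept, dropped = filter_by_tsl(deduped, tsl_table, config.tsl_cutoff)
    else:
        kept, dropped = list(deduped), []

    summary = summarize(kept, n_skipped=match.n_skipped)
    summary["n_conserved"] = conserved
    summary["n_dropped_tsl"] = len(dropped)
    stage_counts = {
        "transcripts_a": len(transcripts_a),
        "transcripts_b": len(transcripts_b),
        "genes_a": len(canon_a),
        "genes_b": len(canon_b),
        "introns_a": len(a_introns),
        "introns_b": len(b_introns),
        "skipped_unmapped": match.n_skipped,
        "unpaired": match.n_unpaired,
        "comparisons": len(match.comparisons),
        "conserved": conserved,
        "candidate_events": len(shifted),
        "unique_groups": len(groups),
        "kept_after_tsl": len(kept),
        "dropped_by_tsl": len(dropped),
    }
    return PipelineResult(
        events=kept,
        dropped=dropped,
        conserved=conserved,
        groups=groups,
        summary=summary,
        stage_counts=stage_counts,
    )
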
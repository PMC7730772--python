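# Methods

## Problem and model

Two genomes A and B descend from a common ancestor. Their exon–intron
boundaries are compared through a pairwise genome alignment that, in
practice, is a collection of local alignments of conserved regions. For
each intron of genome A's canonical isoforms the two boundary positions are
projected onto B and compared with B's annotated introns. Writing
Δs and Δe for the signed offsets between the same-type borders (B minus
projected A, in A's reading direction), a matched pair is *conserved*
(Δs = Δe = 0), *sliding* (Δs = Δe, 1 ≤ |Δs| ≤ `max_shift`) or a
*non-equal shift* (Δs ≠ Δe, both within the bound). Sliding leaves intron
length intact; a non-equal shift changes it, and the net exon-length change
Δs − Δe is frame-preserving iff divisible by three.

The model makes no claim about mechanism or biological reality: it flags
annotation-level boundary differences that survive the alignment, which is
exactly the candidate set a curator then has to triage against
transcriptome evidence. The TSL filter and the free-text `evidence` column
in the output tables exist for that triage; no automated RNA-seq support is
computed.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `max_shift` | 5 bp | upper bound on each border offset; longer relocations are better explained as intron loss plus gain and are deliberately invisible |
| `tsl_cutoff` | 3 | keep events whose reference transcript has TSL ≤ cutoff; TSL4/5/NA mark predicted transcripts and never pass; `None` disables |
| `dedup_flank` | 20 bp | length of the A-side intron flanks hashed for the alternative-locus collapse |

Canonical isoform = the transcript of a gene with the most introns. The
tie-break (larger summed exon length, then smallest transcript id) and the
gene delimitation (the annotation's `name2`/gene field; transcripts without
one form singleton genes) are this package's own conventions — any
deterministic rule works, but one must be fixed for reproducibility.

## Coordinate and orientation conventions

* Everything in memory is 0-based half-open (genePred native); AXT's
  1-based inclusive headers are converted at parse time, and minus-strand
  AXT query coordinates are normalised to B plus-strand positions during
  block decomposition (this needs the B chromosome length, taken from the
  B FASTA).
* A coordinate exactly at a block's exclusive edge is unmapped — no ±1
  guessing. The detector therefore projects the first and last intronic
  bases (both interior points of the locus) and reconstructs the half-open
  borders from them; the arithmetic is identical, the edge case vanishes.
* Where chained alignment records overlap on A, point lookups use the
  record with the highest score, ties to the earliest record in the file.
* Under an inversion (B locus on the minus strand) an A start border
  corresponds to a B end border; border types are mapped through the flip
  and delta signs stay expressed in A's reading direction, so the equal-
  shift test means the same thing in both orientations.
* If several B introns fall within the bound, the one minimising
  |Δs| + |Δe| wins (tie: smaller B start); competitors are logged, not
  silently dropped. One-sided non-equal events (exactly one border moved)
  are retained and flagged, since they may equally be alternative
  donor/acceptor sites.

## Deduplication

Raw events overcount: the same reference intron change recurs against
every aligned partner context, and assemblies carry alternative loci with
byte-identical gene copies. Events are merged (union–find) when they share
(i) the reference gene, intron index and (Δs, Δe) signature, or (ii)
identical reference-side flanks of `dedup_flank` bp on both sides of the
intron together with the same signature. Each group reports one
representative plus its member count; deduplicated count ≤ raw count, with
equality when all signatures are distinct.

## What the synthetic generator emulates

`synthetic_data` builds an ancestor genome of `n_genes` (default 20) genes
— 2–5 introns of 80–300 bp between exons of 60–180 bp, separated by
200–400 bp intergenic spacers, ~30% of genes on the minus strand, all
introns GT–AG by construction, each gene coding over its full span and
carrying an extra truncated isoform with probability 0.7 so canonical
selection is exercised. Genome B then differs by:

* per-site substitutions (default 2%, a plausible divergence for the
  mammal-scale comparisons the detector targets), kept ≥8 bp away from
  annotated boundaries and out of planted gene bodies so planted events are
  the only boundary-affecting differences;
* intergenic indels (default 5×10⁻⁴ per site, 1–10 bp), which exercise
  gapped projection without touching gene structure (a `genic_indels` flag
  exists for stress tests);
* planted events: equal shifts by the `mutation` mechanism (boundaries move
  by d; ≤4 point edits re-create GT–AG at the new positions) or the
  `cut_paste` mechanism (the intron block moves intact, the displaced exon
  bases hop across it — spliced transcript unchanged, phase shifted by d),
  and non-equal shifts (borders moved independently, mutation-style edits);
* optional unaligned windows around one boundary of a chosen fraction of
  genes, yielding a known skipped-border count;
* TSL labels: planted transcripts TSL1 by default (or TSL5 under
  `planted_low_tsl`), decoy labels 4/5/NA for a configurable fraction of
  the rest.

Both planting mechanisms preserve sequence length, so the emitted AXT —
constructed from the known edit history, not re-aligned — stays gapless at
each planted locus. All randomness flows from one seed through
purpose-keyed spawned streams; the same seed reproduces every file byte for
byte.

What the generator does **not** model: rearrangements or inversions (the
emitted alignments are colinear; inverted-locus handling is exercised by
hand-built records in the tests), realistic substitution processes, splice-
site sequence context beyond the terminal dinucleotides, genuinely
ambiguous alignments, and annotation error — the very thing that dominates
real candidate lists. Passing tests therefore show the *pipeline arithmetic*
is right (recovery of known events under noise), not that real detections
are biologically real.

## Numerical and degenerate-input choices

Projection is exact integer arithmetic; there are no tolerances. A
single-exon transcript yields no introns; an empty B annotation yields an
empty report with non-zero unpaired counters and success. Introns whose two
borders project to different chromosomes or orientations are counted as
skipped. Output rows are sorted by (gene id, reference intron start), so
identical inputs give byte-identical outputs.

## Problem sizes used in the checks

The test suite and acceptance script run on generated pairs of 10–20 genes
(roughly 40–70 kb per genome), 20 independent seeds for the noisy-recovery
check and 1000 randomized gapped records for the projection-oracle check —
sizes at which every check is exhaustive over all coordinates involved.

## Known limitations

* Correspondence between introns is purely positional via the alignment;
  no orthology or protein-level validation.
* TSL filtering applies to the reference side only, mirroring the
  triage workflow the output feeds (reference-centric curation).
* The 5 bp bound, the canonical-isoform tie-break and the overlap rule are
  conventions; all are configurable or documented rather than hidden.
* GTF/GFF3 input is out of scope (convert upstream); chain/net and MAF
  alignment formats are not read.
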
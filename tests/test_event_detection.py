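"""Intron matching, shift classification, annotation and deduplication."""

import pytest

from intronslide import (
    AlignmentBlock,
    BlockMap,
    BorderComparison,
    Intron,
    SimParams,
    annotate_event,
    canonical_by_gene,
    classify_shift,
    deduplicate,
    derive_genome_b,
    detect_events,
    extract_introns,
    generate_ancestor,
    match_intron_pairs,
)
from .conftest import identity_map, make_planted_params, make_transcript


def a_intron(start, end, tid="txA", idx=0, chrom="chrA1", strand="+"):
    return Intron(tid, idx, chrom, strand, start, end)


def b_intron(start, end, tid="txB", idx=0, chrom="chrB1", strand="+"):
    return Intron(tid, idx, chrom, strand, start, end)


class TestMatchIntronPairs:
    def test_identity_pair_has_zero_deltas(self):
        res = match_intron_pairs(
            [a_intron(1000, 1500)], [b_intron(1000, 1500)], identity_map(2000)
        )
        [c] = res.comparisons
        assert (c.delta_start, c.delta_end) == (0, 0)
        assert res.n_skipped == 0

    def test_beyond_bound_is_not_a_comparison(self):
        res = match_intron_pairs(
            [a_intron(1000, 1500)], [b_intron(1100, 1600)], identity_map(2000)
        )
        assert res.comparisons == [] and res.n_unpaired == 1

    def test_unmapped_border_is_skipped_and_counted(self):
        # alignment covers only the second half of the intron
        bmap = BlockMap([AlignmentBlock("chrA1", 1200, "chrB1", 1200, 800)])
        res = match_intron_pairs(
            [a_intron(1000, 1500)], [b_intron(1000, 1500)], bmap
        )
        assert res.comparisons == [] and res.n_skipped == 1

    def test_nearest_candidate_wins_and_competitor_logged(self):
        res = match_intron_pairs(
            [a_intron(1000, 1500)],
            [b_intron(1002, 1502, tid="far"), b_intron(1001, 1501, tid="near")],
            identity_map(2000),
        )
        [c] = res.comparisons
        assert c.b_intron.transcript_id == "near"
        assert [d.b_intron.transcript_id for d in res.discarded] == ["far"]

    def test_tie_broken_by_smaller_b_start(self):
        res = match_intron_pairs(
            [a_intron(1000, 1500)],
            [b_intron(1001, 1501), b_intron(999, 1499)],
            identity_map(2000),
        )
        assert res.comparisons[0].b_intron.start == 999

    def test_inverted_b_locus_reconciles_border_types(self):
        # A [0,40) aligns to B plus-strand [0,40) inverted; an unshifted
        # B intron occupies the mirror interval of the A intron.
        block = AlignmentBlock("chrA1", 0, "chrB1", 0, 40, b_strand="-")
        bmap = BlockMap([block])
        a = a_intron(10, 20)
        res = match_intron_pairs([a], [b_intron(20, 30)], bmap)
        [c] = res.comparisons
        assert (c.delta_start, c.delta_end) == (0, 0)
        assert c.b_orientation == "-"
        # B intron shifted by +1 in A's reading direction = -1 on B plus
        res2 = match_intron_pairs([a], [b_intron(19, 29)], bmap)
        assert (res2.comparisons[0].delta_start, res2.comparisons[0].delta_end) == (1, 1)


class TestClassifyShift:
    @pytest.mark.parametrize(
        "ds,de,kind,shift,net,frame,one_sided",
        [
            (1, 1, "SLIDING", 1, 0, None, False),
            (0, 0, "CONSERVED", None, 0, None, False),
            (-1, 1, "NONEQUAL", None, -2, False, False),
            (-5, -5, "SLIDING", 5, 0, None, False),
            (2, -1, "NONEQUAL", None, 3, True, False),
            (0, 3, "NONEQUAL", None, -3, True, True),
        ],
    )
    def test_classification_table(self, ds, de, kind, shift, net, frame, one_sided):
        c = BorderComparison(a_intron(100, 500), b_intron(100 + ds, 500 + de), ds, de)
        e = classify_shift(c)
        assert (e.kind, e.shift_length, e.net_exon_change) == (kind, shift, net)
        assert (e.frame_preserving, e.one_sided) == (frame, one_sided)

    def test_sliding_never_changes_exon_balance(self):
        for d in range(-5, 6):
            if d == 0:
                continue
            c = BorderComparison(a_intron(100, 500), b_intron(100 + d, 500 + d), d, d)
            e = classify_shift(c)
            assert e.kind == "SLIDING" and e.net_exon_change == 0

    def test_oversized_delta_rejected(self):
        c = BorderComparison(a_intron(100, 500), b_intron(106, 506), 6, 6)
        with pytest.raises(ValueError):
            classify_shift(c)


class TestAnnotateEvent:
    def build(self, d=1):
        intron_a = "GT" + "A" * 26 + "AG"
        seq_a = "ATG" + intron_a + "C" * 30
        # cut-and-paste by d: first d downstream-exon bases hop the intron
        seq_b = seq_a[:3] + seq_a[33 : 33 + d] + intron_a + seq_a[33 + d :]
        ta = make_transcript([(0, 3), (33, 63)], tid="txA", gene="gA",
                             chrom="chrA1", cds=(0, 63))
        tb = make_transcript([(0, 3 + d), (33 + d, 63)], tid="txB", gene="gB",
                             chrom="chrB1", cds=(0, 63))
        c = BorderComparison(extract_introns(ta)[0], extract_introns(tb)[0], d, d)
        return (classify_shift(c), {"chrA1": seq_a}, {"chrB1": seq_b},
                {"txA": ta}, {"txB": tb})

    def test_phase_arithmetic_for_planted_slide(self):
        e, ga, gb, tsa, tsb = self.build(d=1)
        e = annotate_event(e, ga, gb, tsa, tsb)
        assert (e.a_phase, e.b_phase) == (0, 1)
        assert e.b_phase == (e.a_phase + e.shift_length) % 3
        assert e.a_gene_id == "gA" and e.b_gene_id == "gB"

    def test_sites_preserved_when_intron_moves_intact(self):
        e, ga, gb, tsa, tsb = self.build(d=2)
        e = annotate_event(e, ga, gb, tsa, tsb)
        assert e.a_sites.canonical and e.b_sites.canonical
        assert e.sites_preserved is True

    def test_missing_sequence_keeps_event(self):
        e, ga, gb, tsa, tsb = self.build()
        e = annotate_event(e, None, {}, tsa, tsb)
        assert e.a_sites is None and e.b_sites is None and e.sites_preserved is None

    def test_frame_flag_on_nonequal(self):
        c = BorderComparison(a_intron(100, 500), b_intron(100, 497), 0, -3)
        e = classify_shift(c)
        assert e.kind == "NONEQUAL" and e.frame_preserving is True


class TestDeduplicate:
    def event(self, gene="g1", idx=0, ds=1, de=1, b_tid="txB", chrom="chr1",
              start=100, a_tid="txA"):
        c = BorderComparison(
            Intron(a_tid, idx, chrom, "+", start, start + 50),
            Intron(b_tid, idx, "chrB1", "+", start + ds, start + 50 + de),
            ds, de,
        )
        from dataclasses import replace

        return replace(classify_shift(c), a_gene_id=gene)

    def test_same_intron_many_partners_collapses(self):
        events = [self.event(b_tid=f"partner{k}") for k in range(6)]
        groups = deduplicate(events)
        assert len(groups) == 1
        assert groups[0].size == 6
        assert all(e.dedup_group == groups[0].group_id for e in groups[0].members)
        assert sum(e.dedup_representative for e in groups[0].members) == 1

    def test_alt_locus_collapse_by_flank_sequence(self):
        # same gene copy annotated on two chromosomes: identical flanks
        seq = "A" * 80 + "GT" + "C" * 46 + "AG" + "T" * 80
        genome = {"chr1": seq, "chr1_alt": seq}
        events = [
            self.event(gene="gA", chrom="chr1", start=80, a_tid="t1"),
            self.event(gene="gA_alt", chrom="chr1_alt", start=80, a_tid="t2"),
        ]
        assert len(deduplicate(events)) == 2  # distinct genes, no sequence
        assert len(deduplicate(events, genome_a=genome)) == 1

    def test_distinct_genes_stay_distinct(self):
        events = [self.event(gene="g1"), self.event(gene="g2", start=400)]
        groups = deduplicate(events)
        assert len(groups) == 2 and all(g.size == 1 for g in groups)

    def test_unique_count_bounded_by_raw_count(self):
        events = [self.event(gene=f"g{k}", start=100 * k + 100) for k in range(5)]
        groups = deduplicate(events)
        assert len(groups) == len(events)  # all-distinct signatures: equality


class TestDetectorOnSyntheticTruth:
    def detect(self, dataset, max_shift=5):
        return detect_events(
            [i for t in canonical_by_gene(dataset.transcripts_a)
             for i in extract_introns(t)],
            [i for t in canonical_by_gene(dataset.transcripts_b)
             for i in extract_introns(t)],
            dataset.block_map(),
            {t.transcript_id: t for t in dataset.transcripts_a},
            {t.transcript_id: t for t in dataset.transcripts_b},
            genome_a=dataset.genome_a,
            genome_b=dataset.genome_b,
            max_shift=max_shift,
        )

    def test_self_comparison_reports_only_conserved(self):
        params = SimParams(n_genes=8, substitution_rate=0.0, indel_rate=0.0, seed=5)
        dataset = derive_genome_b(generate_ancestor(params), params)
        events, match = self.detect(dataset)
        assert events and all(e.kind == "CONSERVED" for e in events)
        assert match.n_skipped == 0

    def test_clean_planted_shifts_recovered_exactly(self):
        ancestor, params = make_planted_params(
            seed=2, n_sliding=6, n_nonequal=0, substitution_rate=0.0,
            indel_rate=0.0,
        )
        dataset = derive_genome_b(ancestor, params)
        events, _ = self.detect(dataset)
        got = sorted(
            (e.a_gene_id, e.comparison.delta_start, e.comparison.delta_end)
            for e in events if e.kind == "SLIDING"
        )
        want = sorted((t.gene_id, t.delta_start, t.delta_end) for t in dataset.truth)
        assert got == want

    def test_noisy_dataset_recovers_truth(self, noisy_dataset):
        events, match = self.detect(noisy_dataset)
        shifted = sorted(
            (e.a_gene_id, e.kind, e.comparison.delta_start, e.comparison.delta_end)
            for e in events if e.kind != "CONSERVED"
        )
        want = sorted(
            (t.gene_id, t.kind, t.delta_start, t.delta_end)
            for t in noisy_dataset.truth
        )
        assert shifted == want
        assert match.n_skipped == noisy_dataset.expected_skipped

    def test_shifts_beyond_bound_invisible_at_default(self):
        params = SimParams(
            n_genes=10, substitution_rate=0.0, indel_rate=0.0, seed=1,
            introns_per_gene=(2, 3), extra_isoform_prob=0.0,
            planted_slidings=[
                (g, 0, g + 1, "mutation" if g % 2 else "cut_paste")
                for g in range(10)
            ],
        )
        dataset = derive_genome_b(generate_ancestor(params), params)
        events, _ = self.detect(dataset)
        lengths = sorted(e.shift_length for e in events if e.kind == "SLIDING")
        assert lengths == [1, 2, 3, 4, 5]
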
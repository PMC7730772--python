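"""Annotation parsing, intron derivation, canonical selection, phases, sites."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from intronslide import (
    GenePredParseError,
    Intron,
    extract_introns,
    intron_phase,
    parse_genepred,
    select_canonical,
    splice_dinucleotides,
    write_genepred,
)
from .conftest import make_transcript


def gp_row(name="tx1", chrom="chr1", strand="+", exons=((10, 100), (200, 300)),
           cds=None, name2=None, bin_col=None):
    tx_start, tx_end = exons[0][0], exons[-1][1]
    cds_start, cds_end = cds if cds else (tx_end, tx_end)
    fields = [
        name, chrom, strand, str(tx_start), str(tx_end),
        str(cds_start), str(cds_end), str(len(exons)),
        "".join(f"{s}," for s, _ in exons), "".join(f"{e}," for _, e in exons),
    ]
    if name2 is not None:
        fields += ["0", name2, "none", "none", "".join("-1," for _ in exons)]
    if bin_col is not None:
        fields = [str(bin_col)] + fields
    return "\t".join(fields)


class TestParseGenepred:
    def test_field_mapping(self):
        [t] = parse_genepred([gp_row(cds=(10, 300))])
        assert t.exons == ((10, 100), (200, 300))
        assert (t.transcript_id, t.chrom, t.strand) == ("tx1", "chr1", "+")
        assert (t.cds_start, t.cds_end) == (10, 300)
        assert t.gene_id == "tx1"  # 10-column form: singleton gene

    def test_noncoding_convention(self):
        [t] = parse_genepred([gp_row(cds=(300, 300))])
        assert t.cds_start is None and not t.is_coding

    def test_exon_list_length_mismatch_names_line(self):
        row = gp_row()
        bad = row.replace("10,200,", "10,150,200,", 1)
        with pytest.raises(GenePredParseError, match="line 1"):
            parse_genepred([bad])

    def test_column_count_mismatch(self):
        with pytest.raises(GenePredParseError, match="line 2"):
            parse_genepred([gp_row(), "only\tfour\tcolumns\there"])

    @pytest.mark.parametrize("dialect,bin_col", [("plain", None), ("binned", 73)])
    def test_dialects_autodetected(self, dialect, bin_col):
        row = gp_row(name2="GENE1", bin_col=bin_col, cds=(10, 300))
        [t] = parse_genepred([row])
        assert t.gene_id == "GENE1"
        [t2] = parse_genepred([row], dialect=dialect)
        assert t2 == t

    def test_roundtrip_through_writer(self):
        transcripts = parse_genepred(
            [gp_row(cds=(10, 300), name2="GENE1"),
             gp_row(name="tx2", strand="-", exons=((0, 50), (80, 120), (400, 500)),
                    cds=(5, 450), name2="GENE2")]
        )
        buf = io.StringIO()
        write_genepred(transcripts, buf)
        buf.seek(0)
        assert sorted(parse_genepred(buf), key=lambda t: t.transcript_id) == sorted(
            transcripts, key=lambda t: t.transcript_id
        )


class TestExtractIntrons:
    def test_plus_strand_gap(self):
        t = make_transcript([(0, 100), (200, 300)])
        assert extract_introns(t) == [Intron("tx1", 0, "chr1", "+", 100, 200)]

    def test_single_exon_has_no_introns(self):
        assert extract_introns(make_transcript([(0, 100)])) == []

    def test_minus_strand_index_reversal(self):
        t = make_transcript([(0, 100), (200, 300), (400, 500)], strand="-")
        introns = extract_introns(t)
        assert [(i.index, i.start, i.end) for i in introns] == [
            (0, 300, 400), (1, 100, 200)
        ]

    def test_span_reconstruction_invariant(self):
        t = make_transcript([(5, 100), (200, 310), (400, 512)], strand="-")
        total = t.exon_length + sum(i.length for i in extract_introns(t))
        assert total == t.span[1] - t.span[0]


class TestSelectCanonical:
    def make(self, tid, n_exons, exon_len=100):
        exons = [(k * 200, k * 200 + exon_len) for k in range(n_exons)]
        return make_transcript(exons, tid=tid)

    def test_most_introns_wins(self):
        a, b = self.make("a", 4), self.make("b", 6)
        assert select_canonical([a, b]) is b

    def test_single_isoform(self):
        a = self.make("a", 2)
        assert select_canonical([a]) is a

    def test_tie_broken_by_exon_length_then_id(self):
        short = make_transcript([(0, 100), (200, 300)], tid="aa")
        long = make_transcript([(0, 150), (200, 350)], tid="zz")
        assert select_canonical([short, long]) is long
        # equal intron count and exon sum: smallest transcript id wins
        twin = make_transcript([(0, 100), (200, 300)], tid="ab")
        assert select_canonical([twin, short]) is short

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            select_canonical([])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.permutations(range(5)))
    def test_permutation_invariant(self, order):
        isoforms = [self.make(f"t{k}", k + 2) for k in range(5)]
        shuffled = [isoforms[i] for i in order]
        assert select_canonical(shuffled) is select_canonical(isoforms)


class TestIntronPhase:
    def test_simple_phase(self):
        t = make_transcript([(0, 100), (200, 300)], cds=(0, 300))
        assert intron_phase(t, 0) == 100 % 3 == 1

    def test_noncoding_is_undefined(self):
        t = make_transcript([(0, 100), (200, 300)])
        assert intron_phase(t, 0) is None

    def test_cds_offset_brute_force(self):
        # oracle: walk genomic positions and count coding exon bases upstream
        t = make_transcript([(0, 100), (200, 300)], cds=(10, 290))
        intron_start = 100
        coding = sum(
            1
            for pos in range(10, 290)
            if pos < intron_start and any(s <= pos < e for s, e in t.exons)
        )
        assert coding == 90
        assert intron_phase(t, 0) == coding % 3 == 0

    def test_minus_strand_counts_downstream_exons(self):
        t = make_transcript([(0, 99), (200, 300)], strand="-", cds=(0, 300))
        # transcription-order intron 0 is the genomic gap; upstream coding
        # bases are the 100 bases of the genomically-last exon
        assert intron_phase(t, 0) == 100 % 3

    def test_utr_intron_undefined(self):
        t = make_transcript([(0, 100), (200, 300), (400, 500)], cds=(250, 450))
        assert intron_phase(t, 0) is None  # entirely in the 5' UTR
        assert intron_phase(t, 1) == (300 - 250) % 3

    def test_bad_index_errors(self):
        t = make_transcript([(0, 100), (200, 300)], cds=(0, 300))
        with pytest.raises(IndexError):
            intron_phase(t, 5)


class TestSpliceDinucleotides:
    def test_plus_strand_canonical(self):
        seq = "GAC" + "gtcctACGTACGTtgag" + "CTAA"
        intron = Intron("t", 0, "c", "+", 3, 20)
        sites = splice_dinucleotides({"c": seq}, intron)
        assert (sites.donor, sites.acceptor, sites.canonical) == ("GT", "AG", True)

    def test_minus_strand_reverse_complemented(self):
        # genomic slice begins CT and ends AC -> GT..AG after revcomp
        seq = "AAA" + "CTxxxxxxAC".replace("x", "G") + "TTT"
        intron = Intron("t", 0, "c", "-", 3, 13)
        sites = splice_dinucleotides({"c": seq}, intron)
        assert (sites.donor, sites.acceptor, sites.canonical) == ("GT", "AG", True)

    def test_noncanonical_pair(self):
        seq = "GAC" + "tacctACGTACGTtgca" + "CTAA"
        intron = Intron("t", 0, "c", "+", 3, 20)
        sites = splice_dinucleotides({"c": seq}, intron)
        assert (sites.donor, sites.acceptor, sites.canonical) == ("TA", "CA", False)

    def test_strand_flip_equivalence(self):
        from Bio.Seq import reverse_complement

        seq = "AACTGGGTTTCCAGTACA"
        intron_m = Intron("t", 0, "c", "-", 4, 14)
        flipped = reverse_complement(seq)
        s, e = len(seq) - 14, len(seq) - 4
        intron_p = Intron("t", 0, "c", "+", s, e)
        assert splice_dinucleotides({"c": seq}, intron_m) == splice_dinucleotides(
            {"c": flipped}, intron_p
        )

    def test_missing_chrom_and_bounds(self):
        intron = Intron("t", 0, "c", "+", 3, 20)
        with pytest.raises(KeyError):
            splice_dinucleotides({}, intron)
        with pytest.raises(ValueError):
            splice_dinucleotides({"c": "ACGT"}, intron)
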
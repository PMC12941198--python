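import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sinetails.formats_io import (
    GenomicInterval,
    parse_gff_features,
    parse_repeatmasker_out,
    extract_sequence,
    read_tail_table,
    reverse_complement,
    write_tail_table,
)
from sinetails.tail_extraction import TailRecord

from conftest import make_annotation

RM_HEADER = (
    "   SW   perc perc perc  query     position in query    matching repeat\n"
    "score   div. del. ins.  sequence  begin  end   (left)  repeat  class/family  begin  end (left) ID\n"
    "\n"
)


def rm_row(begin=101, end=300, strand="+", div=12.5, chrom="chr1",
           repeat="SINEA1", element_id="7"):
    return (
        f"  225 {div}  0.0  0.0  {chrom}  {begin}  {end}  (500)  {strand}  "
        f"{repeat}  SINE/tRNA  1  200  (0)  {element_id}\n"
    )


class TestParseRepeatMaskerOut:
    def test_coordinate_and_strand_and_divergence_conventions(self):
        text = RM_HEADER + rm_row(begin=101, end=300, strand="+", div=12.5) + rm_row(
            begin=50, end=120, strand="C", div=0.0, element_id="8"
        )
        anns = parse_repeatmasker_out(io.StringIO(text))
        assert len(anns) == 2
        assert (anns[0].interval.start, anns[0].interval.end) == (100, 300)
        assert anns[0].interval.strand == "+"
        assert anns[0].divergence_D == pytest.approx(0.125)
        assert anns[0].element_id == "7"
        assert anns[1].interval.strand == "-"

    def test_trailing_overlap_asterisk_tolerated(self):
        text = RM_HEADER + rm_row().rstrip("\n") + " *\n"
        anns = parse_repeatmasker_out(io.StringIO(text))
        assert anns[0].element_id == "7"

    def test_empty_file_after_headers(self):
        assert parse_repeatmasker_out(io.StringIO(RM_HEADER)) == []

    def test_malformed_row_names_line_number(self):
        text = RM_HEADER + rm_row() + "garbage row\n"
        with pytest.raises(ValueError, match="line 5"):
            parse_repeatmasker_out(io.StringIO(text))

    def test_roundtrip_with_writer(self):
        from sinetails.synthetic_fixtures import write_repeatmasker_out

        anns = [make_annotation(start=99, end=399, strand="-", divergence=0.05)]
        buf = io.StringIO()
        write_repeatmasker_out(anns, buf)
        buf.seek(0)
        parsed = parse_repeatmasker_out(buf)
        assert parsed[0].interval == anns[0].interval
        assert parsed[0].divergence_D == pytest.approx(0.05, abs=1e-3)


class TestExtractSequence:
    GENOME = {"chr1": "acgtACGTNNacgtACGT" + "CTTTCTTTATTTATTT"}

    def test_plus_strand_is_uppercased_identity_slice(self):
        iv = GenomicInterval("chr1", 0, 8, "+")
        assert extract_sequence(self.GENOME, iv) == "ACGTACGT"

    def test_minus_strand_reverse_complement_of_documented_insertion(self):
        # The documented 16-bp insertion: reference strand CTTTCTTTATTTATTT,
        # gene-coding strand AAATAAATAAAGAAAG.
        iv = GenomicInterval("chr1", 18, 34, "-")
        assert extract_sequence(self.GENOME, iv) == "AAATAAATAAAGAAAG"

    def test_length_matches_interval(self):
        iv = GenomicInterval("chr1", 3, 11, "-")
        assert len(extract_sequence(self.GENOME, iv)) == len(iv)

    def test_unknown_chromosome_and_out_of_bounds(self):
        with pytest.raises(KeyError):
            extract_sequence(self.GENOME, GenomicInterval("chrX", 0, 5))
        with pytest.raises(ValueError):
            extract_sequence(self.GENOME, GenomicInterval("chr1", 0, 10_000))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_reverse_complement_is_an_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


GFF = """##gff-version 3
chr1\tt\tgene\t1\t300\t.\t+\t.\tID=g1
chr1\tt\tmRNA\t1\t300\t.\t+\t.\tID=t1;Parent=g1
chr1\tt\texon\t1\t100\t.\t+\t.\tParent=t1
chr1\tt\texon\t201\t300\t.\t+\t.\tParent=t1
chr1\tt\tCDS\t21\t100\t.\t+\t0\tParent=t1
chr1\tt\tfive_prime_UTR\t1\t20\t.\t+\t.\tParent=t1
chr1\tt\tgene\t601\t700\t.\t-\t.\tID=g2
chr1\tt\tmRNA\t601\t700\t.\t-\t.\tID=t2;Parent=g2
chr1\tt\texon\t601\t700\t.\t-\t.\tParent=t2
"""


class TestParseGff:
    def test_intron_is_gap_between_exons(self):
        fs = parse_gff_features(io.StringIO(GFF), {"chr1": 1000})
        assert len(fs.introns) == 1
        intron = fs.introns[0]
        assert (intron.start, intron.end) == (100, 200)

    def test_single_exon_gene_has_no_intron(self):
        fs = parse_gff_features(io.StringIO(GFF), {"chr1": 1000})
        g2_introns = [iv for iv in fs.introns if iv.start >= 600]
        assert g2_introns == []

    def test_intergenic_complement_matches_per_base_oracle(self):
        fs = parse_gff_features(io.StringIO(GFF), {"chr1": 1000})
        genic = bytearray(1000)
        for iv in fs.genes:
            for i in range(iv.start, iv.end):
                genic[i] = 1
        oracle = {i for i in range(1000) if not genic[i]}
        derived = set()
        for iv in fs.intergenic:
            derived.update(range(iv.start, iv.end))
        assert derived == oracle

    def test_overlapping_genes_excluded_from_intergenic(self):
        gff = (
            "chr1\tt\tgene\t101\t300\t.\t+\t.\tID=a\n"
            "chr1\tt\tgene\t201\t400\t.\t+\t.\tID=b\n"
        )
        fs = parse_gff_features(io.StringIO(gff), {"chr1": 500})
        spans = sorted((iv.start, iv.end) for iv in fs.intergenic)
        assert spans == [(0, 100), (400, 500)]

    def test_orphan_exon_skipped_with_warning(self, caplog):
        gff = "chr1\tt\texon\t1\t100\t.\t+\t.\tParent=missing\n"
        with caplog.at_level("WARNING"):
            fs = parse_gff_features(io.StringIO(gff))
        assert fs.exons == []
        assert "no resolvable gene" in caplog.text

    def test_gtf_dialect_gene_id(self):
        gtf = (
            'chr1\tt\tgene\t1\t200\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tt\texon\t1\t80\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tt\texon\t121\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        fs = parse_gff_features(io.StringIO(gtf))
        assert len(fs.exons) == 2
        assert [(iv.start, iv.end) for iv in fs.introns] == [(80, 120)]


class TestTailTableRoundTrip:
    def _records(self, n=20):
        records = []
        for i in range(n):
            ann = make_annotation(
                start=100 * i, end=100 * i + 50,
                strand="+" if i % 2 else "-",
                divergence=0.01 * i, element_id=str(i),
            )
            records.append(
                TailRecord(
                    annotation=ann,
                    tail_seq="A" * (i + 1),
                    method="cutoff_exact",
                    tail_interval=ann.interval,
                    category="A-rich",
                )
            )
        return records

    def test_write_read_round_trip(self):
        records = self._records()
        buf = io.StringIO()
        write_tail_table(records, buf)
        buf.seek(0)
        back = read_tail_table(buf)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.annotation == b.annotation
            assert (a.tail_seq, a.method, a.category) == (b.tail_seq, b.method, b.category)
            assert a.tail_interval == b.tail_interval

    def test_empty_list_writes_header_only(self):
        buf = io.StringIO()
        write_tail_table([], buf)
        assert buf.getvalue().count("\n") == 1

    def test_empty_tail_seq_round_trips(self):
        rec = self._records(1)[0]
        rec.tail_seq = ""
        buf = io.StringIO()
        write_tail_table([rec], buf)
        buf.seek(0)
        assert read_tail_table(buf)[0].tail_seq == ""

    def test_header_mismatch_raises(self):
        with pytest.raises(ValueError, match="header"):
            read_tail_table(io.StringIO("wrong\theader\n"))
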
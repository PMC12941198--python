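import io

import numpy as np
import pytest

from sinetails.comparative_variation import (
    CALL_COMPOSITION_CHANGE,
    CALL_IDENTICAL,
    CALL_LENGTH_VARIANT,
    CALL_PRESENCE_ABSENCE,
    PafAlignment,
    align_locus,
    call_polymorphism,
    liftover_interval,
    make_aligner,
    parse_cigar,
    parse_paf,
)
from sinetails.examples import VWA8_INSERTION_GENE_STRAND, VWA8_INSERTION_REF_STRAND
from sinetails.formats_io import GenomicInterval


def identity_paf(length=1000, name="chr1"):
    return PafAlignment(
        query_name=name, query_length=length, query_start=0, query_end=length,
        strand="+", target_name=name, target_length=length, target_start=0,
        target_end=length, cigar=((length, "M"),),
    )


class TestPafParsing:
    def test_round_trip_through_text(self):
        aln = PafAlignment(
            query_name="v", query_length=120, query_start=0, query_end=116,
            strand="+", target_name="chr1", target_length=100, target_start=0,
            target_end=100, cigar=((40, "M"), (16, "I"), (60, "M")),
        )
        parsed = parse_paf(io.StringIO(aln.to_line() + "\n"))[0]
        assert parsed == aln

    def test_cigar_must_consume_spans(self):
        with pytest.raises(ValueError, match="consumes"):
            PafAlignment(
                query_name="v", query_length=100, query_start=0, query_end=100,
                strand="+", target_name="t", target_length=100, target_start=0,
                target_end=100, cigar=((50, "M"),),
            )

    def test_missing_cigar_tag_rejected(self):
        line = "\t".join(map(str, ["q", 10, 0, 10, "+", "t", 10, 0, 10, 10, 10, 60]))
        with pytest.raises(ValueError, match="cg:Z"):
            parse_paf(io.StringIO(line + "\n"))

    def test_malformed_cigar_rejected(self):
        with pytest.raises(ValueError, match="malformed cigar"):
            parse_cigar("10M4Q")


class TestLiftover:
    def test_identity_alignment_is_identity_for_every_interval(self):
        paf = [identity_paf()]
        rng = np.random.default_rng(5)
        for _ in range(50):
            start = int(rng.integers(0, 990))
            iv = GenomicInterval("chr1", start, start + int(rng.integers(1, 10)))
            assert liftover_interval(iv, paf) == iv

    def test_upstream_insertion_shifts_locus_by_plus_16(self):
        # 16-bp insertion in the query at reference position 40.
        aln = PafAlignment(
            query_name="v", query_length=116, query_start=0, query_end=116,
            strand="+", target_name="chr1", target_length=100, target_start=0,
            target_end=100, cigar=((40, "M"), (16, "I"), (60, "M")),
        )
        lifted = liftover_interval(GenomicInterval("chr1", 50, 60), [aln])
        assert (lifted.start, lifted.end) == (66, 76)
        assert lifted.chrom == "v"

    def test_locus_inside_deleted_block_is_unmapped(self):
        aln = PafAlignment(
            query_name="v", query_length=80, query_start=0, query_end=80,
            strand="+", target_name="chr1", target_length=100, target_start=0,
            target_end=100, cigar=((40, "M"), (20, "D"), (40, "M")),
        )
        assert liftover_interval(GenomicInterval("chr1", 45, 55), [aln]) is None
        # Downstream locus shifts left by the deletion length.
        lifted = liftover_interval(GenomicInterval("chr1", 70, 80), [aln])
        assert (lifted.start, lifted.end) == (50, 60)

    def test_strand_reversed_alignment_flips_interval(self):
        # Query aligned reverse-complemented: target base t maps to
        # query position qend - t - 1 for a full-length match.
        aln = PafAlignment(
            query_name="v", query_length=100, query_start=0, query_end=100,
            strand="-", target_name="chr1", target_length=100, target_start=0,
            target_end=100, cigar=((100, "M"),),
        )
        lifted = liftover_interval(GenomicInterval("chr1", 10, 20, "+"), [aln])
        assert (lifted.start, lifted.end) == (80, 90)
        assert lifted.strand == "-"

    def test_outside_all_alignments_unmapped(self):
        aln = identity_paf(length=100)
        assert liftover_interval(GenomicInterval("chr1", 150, 160), [aln]) is None
        assert liftover_interval(GenomicInterval("chr2", 10, 20), [aln]) is None

    def test_consistency_with_generated_variant_assembly(self):
        from sinetails.synthetic_fixtures import AssemblyEdit, make_variant_assembly

        rng = np.random.default_rng(13)
        base = {"chr1": "".join(rng.choice(list("ACGT"), size=500))}
        edits = [
            AssemblyEdit("chr1", 100, insert="TTTTTTTT"),       # +8
            AssemblyEdit("chr1", 200, delete=5),                # -5
            AssemblyEdit("chr1", 300, insert=VWA8_INSERTION_REF_STRAND),  # +16
        ]
        variant, paf = make_variant_assembly(base, edits)
        # A locus downstream of all edits shifts by the net +19.
        lifted = liftover_interval(GenomicInterval("chr1", 400, 420), paf)
        assert (lifted.start, lifted.end) == (419, 439)
        assert variant["chr1"][lifted.start:lifted.end] == base["chr1"][400:420]


class TestAlignLocus:
    def test_identical_sequences_score_and_gapless(self):
        ref = "ACGTACGTACGT"
        result = align_locus(ref, {"a": ref})["a"]
        assert result.score == 2 * len(ref)
        assert "-" not in result.ref_aligned + result.other_aligned
        assert result.ref_aligned_fraction == 1.0

    def test_sixteen_bp_insertion_opens_single_gap_in_reference_row(self):
        ref = "AAATAAAT" + "AAAGAAAG"
        var = ref[:8] + VWA8_INSERTION_GENE_STRAND + ref[8:]
        result = align_locus(ref, {"banna": var})["banna"]
        assert result.ref_aligned.count("-") == 16
        assert result.other_aligned.count("-") == 0
        assert len(result.other_aligned) == len(ref) + 16

    def test_disjoint_sequences_still_return_alignment(self):
        result = align_locus("AAAA", {"x": "GGGG"})["x"]
        assert len(result.ref_aligned) == len(result.other_aligned)

    def test_self_alignment_score_is_maximal(self):
        rng = np.random.default_rng(3)
        aligner = make_aligner()
        s = "".join(rng.choice(list("ACGT"), size=40))
        self_score = align_locus(s, {"s": s}, aligner)["s"].score
        for _ in range(10):
            t = "".join(rng.choice(list("ACGT"), size=40))
            assert align_locus(s, {"t": t}, aligner)["t"].score <= self_score

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            align_locus("", {"x": "AAA"})


class TestCallPolymorphism:
    REF = "AAATAAATAAAGAAAGAAAA"

    def test_all_identical(self):
        seqs = {f"a{i}": self.REF for i in range(9)}
        call = call_polymorphism("L1", self.REF, seqs)
        assert call.call == CALL_IDENTICAL

    def test_nine_reference_one_insertion_is_plus_16_length_variant(self):
        seqs = {f"a{i}": self.REF for i in range(8)}
        seqs["banna"] = self.REF[:10] + VWA8_INSERTION_GENE_STRAND + self.REF[10:]
        call = call_polymorphism("VWA8", self.REF, seqs)
        assert call.call == CALL_LENGTH_VARIANT
        assert call.length_delta["banna"] == 16

    def test_unmapped_assembly_gives_presence_absence(self):
        seqs = {"a1": self.REF, "a2": None}
        call = call_polymorphism("L2", self.REF, seqs)
        assert call.call == CALL_PRESENCE_ABSENCE
        assert call.sequences["a2"] is None

    def test_truncated_sequence_counts_absent(self):
        # Only 6 of 20 reference bases can align to a 6-bp remnant: below the
        # 50% presence threshold the locus is effectively lost.
        seqs = {"a1": self.REF, "a2": self.REF[:6]}
        call = call_polymorphism("L3", self.REF, seqs, presence_min_frac=0.5)
        assert call.call == CALL_PRESENCE_ABSENCE

    def test_composition_change_same_length(self):
        ref = "ATATATATATATATATATAT"        # (AT)n
        var = "ACACACACACACACACACAC"        # (AC)n, same length
        call = call_polymorphism("L4", ref, {"a1": ref, "a2": var},
                                 presence_min_frac=0.3)
        assert call.call == CALL_COMPOSITION_CHANGE
        assert call.categories["a2"] == "(AC)n"

    def test_requires_two_assemblies(self):
        with pytest.raises(ValueError):
            call_polymorphism("L5", self.REF, {})

    def test_presence_absence_outranks_length_variant(self):
        seqs = {"a1": None, "a2": self.REF + "AAAA"}
        call = call_polymorphism("L6", self.REF, seqs)
        assert call.call == CALL_PRESENCE_ABSENCE
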
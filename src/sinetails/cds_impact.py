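"""Coding-sequence impact of tail insertions: splice, translate, compare.

Reconstructs a transcript's mRNA from genomic exon coordinates with optional
insertion edits, finds the longest ATG-initiated open reading frame across
all six reading frames, translates it with the standard genetic code, and
compares reference and variant proteins. An insertion whose length is not a
multiple of three shifts the reading frame of every downstream codon; the
comparison reports the global-alignment percent identity (identities over
alignment columns, gaps included in the denominator), the first divergent
residue, and the frameshift flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from sinetails.comparative_variation import make_aligner
from sinetails.formats_io import GenomicInterval, reverse_complement

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: ordered exons on one strand, optional CDS span."""

    transcript_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        ordered = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError("exons must be non-overlapping")


@dataclass(frozen=True)
class OrfHit:
    """An open reading frame: ATG..stop on one of six frames.

    ``frame`` is 0-2 on the forward strand, 3-5 on the reverse complement;
    ``start``/``end`` index the mRNA of that orientation, with the stop
    codon included in the span.
    """

    frame: int
    start: int
    end: int
    seq: str

    @property
    def reverse(self) -> bool:
        return self.frame >= 3


@dataclass(frozen=True)
class ProteinComparison:
    ref_length: int
    var_length: int
    percent_identity: float
    first_divergent_position: Optional[int]
    frameshift: bool
    insertion_len_mod3: int


def build_mrna(
    genome: Mapping[str, object],
    transcript: TranscriptModel,
    edits: Sequence[tuple[int, str]] = (),
) -> str:
    """Splice a transcript's mRNA, applying insertion edits.

    ``edits`` are ``(position, inserted_sequence)`` pairs in reference genome
    coordinates: the sequence is inserted before ``position`` on the forward
    strand. Exon slices are concatenated 5'->3' (reverse-complemented for
    ``-`` strand transcripts) after edits are applied, so an exonic insertion
    lengthens the mRNA by its length regardless of strand. Edits outside
    every exon are ignored with a warning.
    """
    exons = sorted(transcript.exons, key=lambda iv: iv.start)
    pieces = []
    for exon in exons:
        seq = str(genome[exon.chrom][exon.start : exon.end]).upper()
        # Apply edits falling inside this exon, right-to-left so earlier
        # offsets stay valid.
        local = sorted(
            (pos - exon.start, ins)
            for pos, ins in edits
            if exon.start <= pos < exon.end
        )
        for offset, ins in reversed(local):
            seq = seq[:offset] + ins.upper() + seq[offset:]
        pieces.append(seq)
    for pos, ins in edits:
        if not any(exon.start <= pos < exon.end for exon in exons):
            logger.warning("edit at %d falls outside every exon; ignored", pos)
    mrna = "".join(pieces)
    if transcript.strand == "-":
        mrna = reverse_complement(mrna)
    return mrna


def _orfs_in_frame(seq: str, frame_offset: int) -> Iterable[tuple[int, int]]:
    """ATG..stop spans (half-open, stop codon included) in one forward frame.

    Spans running off the sequence end without a stop codon do not count as
    open reading frames.
    """
    start = None
    for i in range(frame_offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if start is None:
            if codon == "ATG":
                start = i
        elif codon in STOP_CODONS:
            yield start, i + 3
            start = None


def find_longest_orf(mrna: str) -> Optional[OrfHit]:
    """Longest ATG-initiated ORF over three forward + three reverse frames.

    Ties prefer forward frames, then the lowest frame index, then the
    leftmost start. Returns None when no frame contains a stop-terminated
    ATG-initiated reading frame.
    """
    mrna = mrna.upper()
    if len(mrna) < 3:
        raise ValueError("sequence must be at least 3 nt")
    best: Optional[OrfHit] = None
    rc = reverse_complement(mrna)
    for frame in range(6):
        oriented = mrna if frame < 3 else rc
        for start, end in _orfs_in_frame(oriented, frame % 3):
            length = end - start
            if best is None or length > best.end - best.start:
                best = OrfHit(frame=frame, start=start, end=end, seq=oriented[start:end])
    return best


def translate(orf_seq: str) -> str:
    """Translate with the standard genetic code, stopping at the first stop.

    Codons containing ambiguity codes translate to ``X``; the trailing stop
    codon (if any) is not included in the protein.
    """
    if len(orf_seq) % 3 != 0:
        raise ValueError(f"ORF length {len(orf_seq)} is not a multiple of 3")
    protein = []
    for i in range(0, len(orf_seq), 3):
        codon = orf_seq[i : i + 3].upper()
        if codon in STOP_CODONS:
            break
        if set(codon) <= set("ACGT"):
            protein.append(str(Seq(codon).translate()))
        else:
            protein.append("X")
    return "".join(protein)


def compare_proteins(
    p_ref: str, p_var: str, insertion_len: int
) -> ProteinComparison:
    """Compare reference and variant proteins from a tail-insertion edit.

    Percent identity is identities over global-alignment columns (gap columns
    count in the denominator). The first divergent position is the 1-based
    reference residue index at the first non-identical alignment column, or
    None for identical proteins. The frameshift flag is purely arithmetic:
    ``insertion_len % 3 != 0``.
    """
    if not p_ref or not p_var:
        raise ValueError("proteins must be non-empty")
    aligner = make_aligner(match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-0.5)
    alignment = aligner.align(p_ref, p_var)[0]
    row_ref, row_var = str(alignment[0]), str(alignment[1])
    identities = sum(1 for a, b in zip(row_ref, row_var) if a == b and a != "-")
    percent = identities / len(row_ref) * 100.0

    first_div: Optional[int] = None
    ref_pos = 0
    for a, b in zip(row_ref, row_var):
        if a != "-":
            ref_pos += 1
        if a != b:
            first_div = ref_pos if a != "-" else ref_pos + 1
            break
    return ProteinComparison(
        ref_length=len(p_ref),
        var_length=len(p_var),
        percent_identity=percent,
        first_divergent_position=first_div,
        frameshift=insertion_len % 3 != 0,
        insertion_len_mod3=insertion_len % 3,
    )


def cds_impact_report(
    genome: Mapping[str, object],
    transcript: TranscriptModel,
    edits: Sequence[tuple[int, str]],
) -> dict:
    """End-to-end impact analysis: splice, ORF, translate, compare.

    Returns mRNA lengths, ORF spans, protein lengths, percent identity, first
    divergent residue and the frameshift flag for the reference transcript
    versus the edited variant.
    """
    ref_mrna = build_mrna(genome, transcript)
    var_mrna = build_mrna(genome, transcript, edits)
    insertion_len = sum(len(ins) for _pos, ins in edits)
    ref_orf = find_longest_orf(ref_mrna)
    var_orf = find_longest_orf(var_mrna)
    if ref_orf is None or var_orf is None:
        raise ValueError("no open reading frame found")
    p_ref = translate(ref_orf.seq)
    p_var = translate(var_orf.seq)
    comparison = compare_proteins(p_ref, p_var, insertion_len)
    return {
        "transcript_id": transcript.transcript_id,
        "ref_mrna_len": len(ref_mrna),
        "var_mrna_len": len(var_mrna),
        "ref_orf": (ref_orf.frame, ref_orf.start, ref_orf.end),
        "var_orf": (var_orf.frame, var_orf.start, var_orf.end),
        "ref_protein": p_ref,
        "var_protein": p_var,
        "ref_protein_len": len(p_ref),
        "var_protein_len": len(p_var),
        "percent_identity": comparison.percent_identity,
        "first_divergent_position": comparison.first_divergent_position,
        "frameshift": comparison.frameshift,
        "insertion_len": insertion_len,
    }
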
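"""Cross-assembly tail comparison: PAF liftover, alignment, polymorphism calls.

Tail loci annotated on a reference assembly are mapped into other assemblies
by walking the cigar strings of whole-genome PAF alignments (query = other
assembly, target = reference), the per-assembly tail sequences are globally
aligned to the reference tail with affine gap penalties, and each locus
receives one primary verdict with the precedence

    presence_absence > length_variant > composition_change > identical.

A lifted sequence counts as absent when the locus is unmapped (an endpoint
falls in a deletion, outside every alignment, or the endpoints land on
different alignment records) or when less than ``presence_min_frac`` of the
reference tail aligns to it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Union

from Bio import Align

from sinetails.formats_io import GenomicInterval
from sinetails.tail_classification import ClassifierConfig, DEFAULT_CONFIG, classify_tail

_CIGAR_RE = re.compile(r"(\d+)([MIDX=])")

#: Cigar ops consuming query / target. ``=``/``X`` are treated as ``M``.
_CONSUMES_QUERY = {"M", "I", "=", "X"}
_CONSUMES_TARGET = {"M", "D", "=", "X"}


@dataclass(frozen=True)
class PafAlignment:
    """One PAF record with a ``cg:Z:`` cigar."""

    query_name: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_length: int
    target_start: int
    target_end: int
    cigar: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        q = sum(n for n, op in self.cigar if op in _CONSUMES_QUERY)
        t = sum(n for n, op in self.cigar if op in _CONSUMES_TARGET)
        if q != self.query_end - self.query_start:
            raise ValueError(
                f"cigar consumes {q} query bases, span is "
                f"{self.query_end - self.query_start}"
            )
        if t != self.target_end - self.target_start:
            raise ValueError(
                f"cigar consumes {t} target bases, span is "
                f"{self.target_end - self.target_start}"
            )

    def to_line(self) -> str:
        n_match = sum(n for n, op in self.cigar if op in ("M", "="))
        aln_len = sum(n for n, _ in self.cigar)
        cg = "".join(f"{n}{op}" for n, op in self.cigar)
        return "\t".join(
            map(
                str,
                (
                    self.query_name,
                    self.query_length,
                    self.query_start,
                    self.query_end,
                    self.strand,
                    self.target_name,
                    self.target_length,
                    self.target_start,
                    self.target_end,
                    n_match,
                    aln_len,
                    60,
                    f"cg:Z:{cg}",
                ),
            )
        )


def parse_cigar(cg: str) -> tuple[tuple[int, str], ...]:
    ops = tuple((int(n), op) for n, op in _CIGAR_RE.findall(cg))
    if "".join(f"{n}{op}" for n, op in ops) != cg:
        raise ValueError(f"malformed cigar {cg!r}")
    return ops


def parse_paf(source: Union[str, Path, IO]) -> list[PafAlignment]:
    """Parse PAF records; the ``cg:Z:`` cigar tag is required."""
    close = isinstance(source, (str, Path))
    handle = open(source, "rt") if close else source
    records = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"PAF line {lineno}: fewer than 12 columns")
            cigar = None
            for tag in fields[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = parse_cigar(tag[5:])
            if cigar is None:
                raise ValueError(f"PAF line {lineno}: missing cg:Z: cigar tag")
            records.append(
                PafAlignment(
                    query_name=fields[0],
                    query_length=int(fields[1]),
                    query_start=int(fields[2]),
                    query_end=int(fields[3]),
                    strand=fields[4],
                    target_name=fields[5],
                    target_length=int(fields[6]),
                    target_start=int(fields[7]),
                    target_end=int(fields[8]),
                    cigar=cigar,
                )
            )
    finally:
        if close:
            handle.close()
    return records


def _map_target_position(aln: PafAlignment, pos: int) -> Optional[int]:
    """Map one target (reference) position through the cigar to the query.

    Returns the forward-strand query coordinate, or None when the position
    falls in a deletion (absent from the query) or outside the aligned span.
    """
    if not (aln.target_start <= pos < aln.target_end):
        return None
    tpos = aln.target_start
    q_consumed = 0
    for length, op in aln.cigar:
        in_t = op in _CONSUMES_TARGET
        in_q = op in _CONSUMES_QUERY
        if in_t and tpos <= pos < tpos + length:
            if not in_q:
                return None  # deleted in the query assembly
            offset = pos - tpos
            if aln.strand == "+":
                return aln.query_start + q_consumed + offset
            return aln.query_end - (q_consumed + offset) - 1
        if in_t:
            tpos += length
        if in_q:
            q_consumed += length
    return None


def liftover_interval(
    interval: GenomicInterval, alignments: Iterable[PafAlignment]
) -> Optional[GenomicInterval]:
    """Lift a reference (target) interval to query-assembly coordinates.

    Both endpoints must map within the same alignment record; strand-reversed
    alignments flip the interval strand. Returns None when unmapped.
    """
    for aln in alignments:
        if aln.target_name != interval.chrom:
            continue
        left = _map_target_position(aln, interval.start)
        right = _map_target_position(aln, interval.end - 1)
        if left is None or right is None:
            continue
        lo, hi = min(left, right), max(left, right)
        if aln.strand == "+":
            strand = interval.strand
        else:
            strand = "-" if interval.strand == "+" else "+"
        return GenomicInterval(aln.query_name, lo, hi + 1, strand)
    return None


@dataclass(frozen=True)
class LocusAlignment:
    """Global pairwise alignment of one assembly's tail to the reference."""

    ref_aligned: str
    other_aligned: str
    score: float

    @property
    def ref_aligned_fraction(self) -> float:
        """Fraction of reference bases aligned to a base (not a gap)."""
        ref_len = sum(1 for c in self.ref_aligned if c != "-")
        if ref_len == 0:
            return 0.0
        aligned = sum(
            1
            for r, o in zip(self.ref_aligned, self.other_aligned)
            if r != "-" and o != "-"
        )
        return aligned / ref_len


def make_aligner(
    match: float = 2.0,
    mismatch: float = -2.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_locus(
    ref_seq: str,
    other_seqs: Mapping[str, str],
    aligner: Optional[Align.PairwiseAligner] = None,
) -> dict[str, LocusAlignment]:
    """Align each assembly's sequence to the reference tail (star layout).

    Exact global alignment with affine gaps (defaults: match +2, mismatch -2,
    gap open -4, gap extend -1); the first optimal alignment reported is used,
    which is deterministic for a fixed scoring scheme.
    """
    if not ref_seq:
        raise ValueError("reference sequence must be non-empty")
    if aligner is None:
        aligner = make_aligner()
    results = {}
    for name, seq in other_seqs.items():
        if not seq:
            results[name] = LocusAlignment(ref_seq, "-" * len(ref_seq), 0.0)
            continue
        alignment = aligner.align(ref_seq, seq)[0]
        results[name] = LocusAlignment(
            ref_aligned=str(alignment[0]),
            other_aligned=str(alignment[1]),
            score=alignment.score,
        )
    return results


CALL_IDENTICAL = "identical"
CALL_PRESENCE_ABSENCE = "presence_absence"
CALL_LENGTH_VARIANT = "length_variant"
CALL_COMPOSITION_CHANGE = "composition_change"


@dataclass
class PolymorphismCall:
    """Per-locus cross-assembly verdict."""

    locus_id: str
    call: str
    sequences: dict[str, Optional[str]] = field(default_factory=dict)
    length_delta: dict[str, Optional[int]] = field(default_factory=dict)
    categories: dict[str, Optional[str]] = field(default_factory=dict)


def call_polymorphism(
    locus_id: str,
    ref_seq: str,
    assembly_seqs: Mapping[str, Optional[str]],
    classifier_config: ClassifierConfig = DEFAULT_CONFIG,
    presence_min_frac: float = 0.5,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> PolymorphismCall:
    """Call the tail polymorphism type for one locus across assemblies.

    ``assembly_seqs`` maps assembly name to the lifted tail sequence, or None
    for unmapped loci. Requires at least two assemblies (the reference counts
    as one and is added implicitly under the name ``reference`` if absent).
    """
    seqs = dict(assembly_seqs)
    if "reference" not in seqs:
        seqs = {"reference": ref_seq, **seqs}
    if len(seqs) < 2:
        raise ValueError("call_polymorphism requires >= 2 assemblies")

    alignments = align_locus(
        ref_seq,
        {name: seq for name, seq in seqs.items() if seq},
        aligner=aligner,
    )
    present: dict[str, str] = {}
    absent: list[str] = []
    for name, seq in seqs.items():
        if not seq or alignments[name].ref_aligned_fraction < presence_min_frac:
            absent.append(name)
        else:
            present[name] = seq

    call = PolymorphismCall(locus_id=locus_id, call=CALL_IDENTICAL)
    call.sequences = {name: (seq or None) for name, seq in seqs.items()}
    call.length_delta = {
        name: (len(seq) - len(ref_seq) if name in present else None)
        for name, seq in seqs.items()
    }
    call.categories = {
        name: (classify_tail(seq, classifier_config) if name in present else None)
        for name, seq in seqs.items()
    }

    if absent:
        call.call = CALL_PRESENCE_ABSENCE
    elif any(delta for delta in call.length_delta.values() if delta):
        call.call = CALL_LENGTH_VARIANT
    elif len({cat for cat in call.categories.values() if cat is not None}) > 1:
        call.call = CALL_COMPOSITION_CHANGE
    return call
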
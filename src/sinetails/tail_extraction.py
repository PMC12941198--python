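"""Locate the SINE body-to-tail boundary and extract the 3' tail.

The boundary between the element body and its adenine-rich tail is marked by
a short "cutoff" motif near the 3' end of the element body. Matching is
hierarchical: an exact pass over the motif library precedes a single-mismatch
(Hamming distance 1) pass, so an exact match of any motif always beats a
mismatched match of any other. Within one motif, the occurrence whose end
lies closest to the 3' end of the element wins: tails are terminal, and a
spurious internal copy of the motif must not truncate the body. Elements in
which no motif matches fall back to designating the terminal 30 bp (the whole
element if shorter) as the tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Optional, Union

from sinetails.formats_io import (
    GenomicInterval,
    SINEAnnotation,
    extract_sequence,
)

#: Extraction methods recorded on each TailRecord.
METHOD_EXACT = "cutoff_exact"
METHOD_MISMATCH1 = "cutoff_mismatch1"
METHOD_FALLBACK = "fallback"

_ACGT = set("ACGT")


@dataclass
class CutoffLibrary:
    """Ordered cutoff motifs per subfamily, with a global wildcard list.

    ``motifs`` maps subfamily name to an ordered motif list; the ``*`` key
    holds global motifs tried when (and after) the subfamily list. The
    per-subfamily list takes priority over the global list within each
    matching pass.
    """

    motifs: dict[str, list[str]] = field(default_factory=dict)
    fallback_length: int = 30

    def __post_init__(self) -> None:
        if self.fallback_length < 1:
            raise ValueError("fallback_length must be >= 1")
        for subfamily, motif_list in self.motifs.items():
            if not motif_list:
                raise ValueError(f"subfamily {subfamily!r} maps to an empty motif list")
            for motif in motif_list:
                if not motif or not set(motif) <= _ACGT:
                    raise ValueError(
                        f"motif {motif!r} for {subfamily!r} is not uppercase ACGT"
                    )

    def motifs_for(self, subfamily: str) -> list[str]:
        """Ordered motifs for a subfamily: its own list, then the global list."""
        own = self.motifs.get(subfamily, [])
        global_ = self.motifs.get("*", [])
        return list(own) + [m for m in global_ if m not in own]

    @classmethod
    def from_tsv(
        cls, source: Union[str, Path, IO], fallback_length: int = 30
    ) -> "CutoffLibrary":
        """Load a plain TSV library: ``subfamily<TAB>motif``, ``*`` wildcard."""
        close = isinstance(source, (str, Path))
        handle = open(source, "rt") if close else source
        motifs: dict[str, list[str]] = {}
        try:
            for lineno, raw in enumerate(handle, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(
                        f"cutoff library line {lineno}: expected subfamily<TAB>motif"
                    )
                subfamily, motif = parts
                motifs.setdefault(subfamily, []).append(motif.upper())
        finally:
            if close:
                handle.close()
        return cls(motifs=motifs, fallback_length=fallback_length)


@dataclass
class TailRecord:
    """An extracted tail in element orientation (5'->3' of the element)."""

    annotation: SINEAnnotation
    tail_seq: str
    method: str
    tail_interval: GenomicInterval
    category: Optional[str] = None
    age: Optional[object] = None


def _hamming_at_most(seq: str, motif: str, offset: int, max_mismatch: int) -> bool:
    mismatches = 0
    for i, base in enumerate(motif):
        if seq[offset + i] != base:
            mismatches += 1
            if mismatches > max_mismatch:
                return False
    return True


def _best_match_end(element_seq: str, motif: str, mismatches: int) -> Optional[int]:
    """End offset of the 3'-most occurrence of motif with exactly this tolerance."""
    m = len(motif)
    for offset in range(len(element_seq) - m, -1, -1):
        if _hamming_at_most(element_seq, motif, offset, mismatches):
            return offset + m
    return None


def locate_cutoff(
    element_seq: str, motifs: list[str], max_mismatch: int = 1
) -> Optional[tuple[int, str]]:
    """Find the body->tail boundary in an element sequence.

    Two passes: pass 1 exact, pass 2 (if ``max_mismatch`` is 1) Hamming
    distance <= 1. Each pass tries motifs in library order; within one motif
    the occurrence whose end is nearest the 3' end wins. Returns ``(tail_start,
    method)`` where ``tail_start`` is the end offset of the matched motif, or
    ``None`` when nothing matches (a valid outcome, not an error).
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    for mismatches, method in ((0, METHOD_EXACT), (1, METHOD_MISMATCH1)):
        if mismatches > max_mismatch:
            break
        for motif in motifs:
            if len(motif) > len(element_seq):
                continue
            end = _best_match_end(element_seq, motif, mismatches)
            if end is not None:
                return end, method
    return None


def tail_genomic_interval(
    annotation: SINEAnnotation, offset_in_element: int, length: int
) -> GenomicInterval:
    """Map an element-orientation tail span back to genomic coordinates.

    For ``+`` elements the tail occupies the right (3') genomic end; for ``-``
    elements the element's 3' end is the left genomic end, and the tail
    sequence is the reverse complement of that genomic slice.
    """
    iv = annotation.interval
    if offset_in_element < 0 or length < 1:
        raise ValueError("offset must be >= 0 and length >= 1")
    if offset_in_element + length > len(iv):
        raise ValueError(
            f"tail span (offset {offset_in_element}, length {length}) exceeds "
            f"element length {len(iv)}"
        )
    if iv.strand == "+":
        start = iv.start + offset_in_element
    else:
        start = iv.end - offset_in_element - length
    return GenomicInterval(iv.chrom, start, start + length, iv.strand)


def extract_tail(
    annotation: SINEAnnotation,
    genome: Mapping[str, object],
    library: CutoffLibrary,
    max_mismatch: int = 1,
) -> TailRecord:
    """Extract the 3' tail of one annotated element.

    If a cutoff motif matches, the tail is everything downstream of the match
    in element orientation (uncapped length); otherwise the terminal
    ``library.fallback_length`` bases (the whole element if shorter) are
    designated as the tail with method ``fallback``.
    """
    element_seq = extract_sequence(genome, annotation.interval)
    if not element_seq:
        raise ValueError(f"element {annotation.element_id} is empty")
    motifs = library.motifs_for(annotation.subfamily)
    hit = locate_cutoff(element_seq, motifs, max_mismatch=max_mismatch)
    if hit is not None and hit[0] < len(element_seq):
        tail_start, method = hit
    else:
        tail_start = max(0, len(element_seq) - library.fallback_length)
        method = METHOD_FALLBACK
    length = len(element_seq) - tail_start
    interval = tail_genomic_interval(annotation, tail_start, length)
    return TailRecord(
        annotation=annotation,
        tail_seq=element_seq[tail_start:],
        method=method,
        tail_interval=interval,
    )
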
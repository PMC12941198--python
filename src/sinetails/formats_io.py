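"""Readers and writers for the external formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals on the
forward strand of the assembly; conversion from the 1-based inclusive
conventions of RepeatMasker ``.out`` and GFF happens only at the parse/write
boundary. Sequences are returned uppercase; ``N`` is permitted and is treated
as a mismatch to every base by downstream motif scanning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Union

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID_STRANDS = ("+", "-")

#: Column order of the tail TSV table. ``D``/``K``/``age_my``/``age_bin`` are
#: empty strings until the aging stage has run (or the element is saturated).
TAIL_TABLE_COLUMNS = (
    "element_id",
    "chrom",
    "start",
    "end",
    "strand",
    "subfamily",
    "method",
    "tail_seq",
    "category",
    "D",
    "K",
    "age_my",
    "age_bin",
)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic span with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SINEAnnotation:
    """One RepeatMasker hit: location, subfamily and proportional divergence."""

    interval: GenomicInterval
    subfamily: str
    divergence_D: float
    element_id: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence_D < 1.0):
            raise ValueError(f"divergence_D must be in [0,1), got {self.divergence_D}")


@dataclass
class GeneFeatureSet:
    """Gene-model intervals plus derived introns and intergenic regions.

    ``introns`` are the per-gene gaps between that gene's (merged) exons;
    ``intergenic`` is the complement of merged gene spans within chromosome
    bounds. Neither contains zero-length intervals.
    """

    genes: list = field(default_factory=list)
    exons: list = field(default_factory=list)
    cds: list = field(default_factory=list)
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)
    introns: list = field(default_factory=list)
    intergenic: list = field(default_factory=list)
    chrom_lengths: dict = field(default_factory=dict)


def _as_text_stream(source: Union[str, Path, IO]) -> IO:
    if isinstance(source, (str, Path)):
        return open(source, "rt")
    return source


def parse_repeatmasker_out(source: Union[str, Path, IO]) -> list[SINEAnnotation]:
    """Parse a RepeatMasker ``.out`` annotation file.

    The dialect is whitespace-delimited with three header lines; columns are
    score, perc div, perc del, perc ins, query, begin, end, (left), strand,
    repeat, class/family, repeat begin, repeat end, (left), ID, and an
    optional ``*`` overlap flag. Coordinates (1-based inclusive) are converted
    to 0-based half-open; strand ``C`` maps to ``-``; perc div is divided by
    100 to a proportion.
    """
    stream = _as_text_stream(source)
    annotations: list[SINEAnnotation] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        # Header lines start with the column banner or its underline.
        if line.startswith(("SW", "score", "bit")):
            continue
        fields = line.split()
        if len(fields) < 14:
            raise ValueError(
                f"malformed RepeatMasker row at line {lineno}: "
                f"expected >=14 whitespace-delimited fields, got {len(fields)}"
            )
        try:
            perc_div = float(fields[1])
            chrom = fields[4]
            begin = int(fields[5])
            end = int(fields[6])
            strand_raw = fields[8]
            repeat = fields[9]
            element_id = fields[14] if len(fields) > 14 else fields[-1]
        except (ValueError, IndexError) as exc:
            raise ValueError(
                f"malformed RepeatMasker row at line {lineno}: {exc}"
            ) from exc
        if strand_raw == "C":
            strand = "-"
        elif strand_raw in _VALID_STRANDS:
            strand = strand_raw
        else:
            raise ValueError(
                f"malformed RepeatMasker row at line {lineno}: "
                f"unknown strand {strand_raw!r}"
            )
        interval = GenomicInterval(chrom=chrom, start=begin - 1, end=end, strand=strand)
        annotations.append(
            SINEAnnotation(
                interval=interval,
                subfamily=repeat,
                divergence_D=perc_div / 100.0,
                element_id=element_id,
            )
        )
    return annotations


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_sequence(genome: Mapping[str, object], interval: GenomicInterval) -> str:
    """Fetch the sequence of ``interval`` in strand orientation.

    ``genome`` may be a ``pyfaidx.Fasta`` handle or any mapping of chromosome
    name to string. Returns the forward slice for ``+`` intervals and the
    reverse complement for ``-`` intervals, always uppercase.
    """
    if interval.chrom not in genome:
        raise KeyError(f"unknown chromosome {interval.chrom!r}")
    record = genome[interval.chrom]
    chrom_len = len(record)
    if interval.end > chrom_len:
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} exceeds "
            f"chromosome length {chrom_len}"
        )
    seq = str(record[interval.start : interval.end]).upper()
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq


_GFF3_ATTR = re.compile(r"(\w+)=([^;]+)")
_GTF_ATTR = re.compile(r'(\w+) "([^"]+)"')

_UTR5_TYPES = {"five_prime_utr", "five_prime_UTR", "5UTR", "5'UTR"}
_UTR3_TYPES = {"three_prime_utr", "three_prime_UTR", "3UTR", "3'UTR"}


def _parse_attributes(attr_field: str) -> dict:
    attrs = dict(_GFF3_ATTR.findall(attr_field))
    attrs.update(_GTF_ATTR.findall(attr_field))
    return attrs


def _merge_intervals(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for start, end in sorted(spans):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def parse_gff_features(
    source: Union[str, Path, IO],
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> GeneFeatureSet:
    """Parse gene/exon/CDS/UTR records from GFF3 or GTF into a GeneFeatureSet.

    Gene identity for sub-features is resolved through the ``Parent`` /
    ``gene_id`` attribute chain (transcripts are followed to their gene).
    Features whose gene cannot be resolved are skipped with a logged warning.
    Introns and intergenic regions are derived here and nowhere else.
    """
    stream = _as_text_stream(source)
    rows = []
    for raw in stream:
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            continue
        seqid, _src, ftype, start, end, _score, strand, _phase, attr_field = fields[:9]
        rows.append(
            (
                seqid,
                ftype,
                int(start) - 1,
                int(end),
                strand if strand in _VALID_STRANDS else "+",
                _parse_attributes(attr_field),
            )
        )

    # Pass 1: genes by ID, transcript -> gene map.
    gene_ids: dict[str, str] = {}
    tx_to_gene: dict[str, str] = {}
    for seqid, ftype, start, end, strand, attrs in rows:
        fid = attrs.get("ID")
        if ftype == "gene":
            gid = fid or attrs.get("gene_id")
            if gid:
                gene_ids[gid] = gid
        elif ftype in ("mRNA", "transcript"):
            tid = fid or attrs.get("transcript_id")
            gid = attrs.get("Parent") or attrs.get("gene_id")
            if tid and gid:
                tx_to_gene[tid] = gid

    def resolve_gene(attrs: dict) -> Optional[str]:
        gid = attrs.get("gene_id")
        if gid:
            return gid
        parent = attrs.get("Parent")
        if parent:
            parent = parent.split(",")[0]
            if parent in tx_to_gene:
                return tx_to_gene[parent]
            if parent in gene_ids:
                return parent
        return None

    fset = GeneFeatureSet(chrom_lengths=dict(chrom_lengths or {}))
    gene_spans: dict[str, list] = {}
    gene_exons: dict[tuple[str, str], list[tuple[int, int]]] = {}
    gene_chrom_strand: dict[str, tuple[str, str]] = {}

    for seqid, ftype, start, end, strand, attrs in rows:
        if end <= start:
            continue
        iv = GenomicInterval(seqid, start, end, strand)
        if ftype == "gene":
            gid = attrs.get("ID") or attrs.get("gene_id") or f"gene:{seqid}:{start}"
            fset.genes.append(iv)
            gene_spans.setdefault(seqid, []).append((start, end))
            gene_chrom_strand[gid] = (seqid, strand)
        elif ftype in ("mRNA", "transcript"):
            continue
        else:
            gid = resolve_gene(attrs)
            if gid is None and ftype in ({"exon", "CDS"} | _UTR5_TYPES | _UTR3_TYPES):
                logger.warning("skipping %s at %s:%d-%d: no resolvable gene", ftype, seqid, start, end)
                continue
            if ftype == "exon":
                fset.exons.append(iv)
                gene_exons.setdefault((gid, seqid), []).append((start, end))
            elif ftype == "CDS":
                fset.cds.append(iv)
            elif ftype in _UTR5_TYPES:
                fset.utr5.append(iv)
            elif ftype in _UTR3_TYPES:
                fset.utr3.append(iv)

    # Derived introns: per-gene gaps between merged exons.
    for (gid, seqid), spans in gene_exons.items():
        merged = _merge_intervals(spans)
        strand = gene_chrom_strand.get(gid, (seqid, "+"))[1]
        for (s1, e1), (s2, _e2) in zip(merged, merged[1:]):
            if s2 > e1:
                fset.introns.append(GenomicInterval(seqid, e1, s2, strand))

    # Derived intergenic: complement of merged gene spans within chrom bounds.
    chroms = set(gene_spans) | set(fset.chrom_lengths)
    for chrom in sorted(chroms):
        bound = fset.chrom_lengths.get(chrom)
        spans = _merge_intervals(gene_spans.get(chrom, []))
        if bound is None:
            bound = spans[-1][1] if spans else 0
        cursor = 0
        for s, e in spans:
            if s > cursor:
                fset.intergenic.append(GenomicInterval(chrom, cursor, s))
            cursor = max(cursor, e)
        if bound > cursor:
            fset.intergenic.append(GenomicInterval(chrom, cursor, bound))
    return fset


def _format_float(value: Optional[float]) -> str:
    return "" if value is None else repr(float(value))


def write_tail_table(records: Iterable, stream: Union[str, Path, IO]) -> None:
    """Serialize TailRecords to TSV with the fixed documented header."""
    close = isinstance(stream, (str, Path))
    out = open(stream, "wt") if close else stream
    try:
        out.write("\t".join(TAIL_TABLE_COLUMNS) + "\n")
        for rec in records:
            iv = rec.tail_interval
            age = rec.age
            row = [
                rec.annotation.element_id,
                iv.chrom,
                str(iv.start),
                str(iv.end),
                iv.strand,
                rec.annotation.subfamily,
                rec.method,
                rec.tail_seq,
                rec.category or "",
                _format_float(rec.annotation.divergence_D),
                _format_float(age.K if age else None),
                _format_float(age.age_my if age else None),
                (age.bin_label if age else ""),
            ]
            out.write("\t".join(row) + "\n")
    finally:
        if close:
            out.close()


def read_tail_table(stream: Union[str, Path, IO]) -> list:
    """Read a tail TSV written by :func:`write_tail_table` (lossless)."""
    from sinetails.age_estimation import AgeEstimate
    from sinetails.tail_extraction import TailRecord

    close = isinstance(stream, (str, Path))
    handle = open(stream, "rt") if close else stream
    try:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != TAIL_TABLE_COLUMNS:
            raise ValueError(
                f"tail table header mismatch: expected {list(TAIL_TABLE_COLUMNS)}, got {header}"
            )
        records = []
        for raw in handle:
            if not raw.strip():
                continue
            vals = dict(zip(TAIL_TABLE_COLUMNS, raw.rstrip("\n").split("\t")))
            interval = GenomicInterval(
                vals["chrom"], int(vals["start"]), int(vals["end"]), vals["strand"]
            )
            annotation = SINEAnnotation(
                interval=interval,
                subfamily=vals["subfamily"],
                divergence_D=float(vals["D"]),
                element_id=vals["element_id"],
            )
            age = None
            if vals["K"]:
                age = AgeEstimate(
                    divergence_D=float(vals["D"]),
                    K=float(vals["K"]),
                    age_my=float(vals["age_my"]),
                    bin_label=vals["age_bin"],
                )
            records.append(
                TailRecord(
                    annotation=annotation,
                    tail_seq=vals["tail_seq"],
                    method=vals["method"],
                    tail_interval=interval,
                    category=vals["category"] or None,
                    age=age,
                )
            )
        return records
    finally:
        if close:
            handle.close()


def write_bed6(records: Iterable, stream: Union[str, Path, IO]) -> None:
    """Export tail intervals as BED6 (name = element_id, score = 0)."""
    close = isinstance(stream, (str, Path))
    out = open(stream, "wt") if close else stream
    try:
        for rec in records:
            iv = rec.tail_interval
            out.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.annotation.element_id}\t0\t{iv.strand}\n"
            )
    finally:
        if close:
            out.close()
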
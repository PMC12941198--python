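"""Seeded synthetic data: genomes with planted SINEs, annotations, variants.

Every generator here is a pure function of its arguments and a seed, so any
fixture can be regenerated exactly. Planted elements are built as

    body (mutated at the requested divergence) + cutoff motif + tail

where the cutoff motif contains no adenine (it is drawn from {C,G,T}) so it
can never collide with the A-based tail motif vocabulary. The mutation model
is substitution-only - each base is replaced with probability ``d``, uniform
over the three alternatives - so the true tail boundary stays well-defined;
indels enter only as explicit assembly edits in
:func:`make_variant_assembly`. Background sequence defaults to GC = 0.42,
the typical value for a mammalian (pig-like) genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from sinetails.formats_io import GenomicInterval, SINEAnnotation, reverse_complement
from sinetails.tail_classification import (
    A_RICH,
    ALL_MOTIFS,
    DEFAULT_CONFIG,
    OTHER,
    SERIES_MOTIFS,
    ClassifierConfig,
    classify_tail,
)
from sinetails.tail_extraction import CutoffLibrary

BASES = np.array(list("ACGT"))

#: Subfamilies of the three pig SINE families.
DEFAULT_SUBFAMILIES = tuple(
    [f"SINEA{i}" for i in range(1, 12)]
    + [f"SINEB{i}" for i in range(1, 7)]
    + [f"SINEC{i}" for i in range(1, 9)]
)

_CUTOFF_ALPHABET = "CGT"


def synthetic_default_library(
    subfamilies: Sequence[str] = DEFAULT_SUBFAMILIES,
    motif_length: int = 10,
    fallback_length: int = 30,
) -> CutoffLibrary:
    """Deterministic synthetic cutoff-motif library (one motif per subfamily).

    Stands in for a curated body/tail boundary motif collection; motifs are
    adenine-free ``motif_length``-mers derived from the subfamily index, plus
    a single ``*`` wildcard motif.
    """
    motifs: dict[str, list[str]] = {}
    for idx, subfamily in enumerate(subfamilies, start=1):
        digits = []
        value = idx
        for _ in range(motif_length - 2):
            digits.append(_CUTOFF_ALPHABET[value % 3])
            value //= 3
        motifs[subfamily] = ["GG" + "".join(digits)]
    motifs["*"] = ["GGTCCGTCCG"[:motif_length]]
    return CutoffLibrary(motifs=motifs, fallback_length=fallback_length)


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.42) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=probs))


def mutate(seq: str, d: float, seed_or_rng: Union[int, np.random.Generator]) -> str:
    """Substitute each base with probability ``d``, uniform over alternatives."""
    if not (0.0 <= d <= 0.5):
        raise ValueError(f"divergence must be in [0, 0.5], got {d}")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < d
    out = arr.copy()
    for i in np.nonzero(hit)[0]:
        alternatives = [b for b in "ACGT" if b != arr[i]]
        out[i] = alternatives[rng.integers(3)]
    return "".join(out)


def _make_composite_tail(series: str, length: int) -> str:
    """Two distinct same-series motifs, each with a tandem run of two."""
    long_motif, short_motif = SERIES_MOTIFS[series][1], SERIES_MOTIFS[series][2]
    core = long_motif * 2 + short_motif * 2
    if length < len(core):
        raise ValueError(
            f"{series}-composite needs length >= {len(core)}, got {length}"
        )
    pad = ("C" if series != "AC" else "G") * (length - len(core))
    return core + pad


def make_tail(
    category: str,
    length: int,
    seed_or_rng: Union[int, np.random.Generator],
    config: ClassifierConfig = DEFAULT_CONFIG,
    max_retries: int = 100,
) -> str:
    """A tail sequence guaranteed to classify as ``category``.

    Constructions are canonical per category (a homopolymer A run for A-rich,
    tandem motif copies for the single-motif categories, two distinct tandem
    motifs for composites, adenine-poor random sequence for Other) and are
    verified against :func:`classify_tail`; Other is re-drawn up to
    ``max_retries`` times if a random draw accidentally matches a category.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if length < 1:
        raise ValueError("length must be >= 1")
    if category == A_RICH:
        if length < config.arich_min_run:
            raise ValueError(f"A-rich needs length >= {config.arich_min_run}")
        tail = "A" * length
    elif category == OTHER:
        for _ in range(max_retries):
            tail = "".join(rng.choice(list("CGT"), size=length))
            if classify_tail(tail, config) == OTHER:
                break
        else:
            raise ValueError(f"could not generate an Other tail of length {length}")
    elif category.endswith("-composite"):
        tail = _make_composite_tail(category.split("-")[0], length)
    elif category.startswith("(") and category.endswith(")n"):
        motif = category[1:-2]
        if motif not in ALL_MOTIFS:
            raise ValueError(f"unknown motif category {category!r}")
        need = config.min_consecutive[len(motif)]
        if length < need * len(motif):
            raise ValueError(
                f"{category} needs length >= {need * len(motif)}, got {length}"
            )
        copies = length // len(motif)
        tail = motif * copies + motif[: length % len(motif)]
    else:
        raise ValueError(f"unknown category {category!r}")
    realized = classify_tail(tail, config)
    if realized != category:
        raise ValueError(
            f"generated tail classifies as {realized}, requested {category}"
        )
    return tail


@dataclass(frozen=True)
class PlantSpec:
    """How to plant copies of one subfamily into a synthetic genome."""

    subfamily: str
    copies: int = 1
    divergence: float = 0.0
    strand: str = "+"
    category: str = A_RICH
    tail_length: int = 20
    cutoff_intact: bool = True
    body_length: int = 200
    consensus: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 0.5):
            raise ValueError("divergence must be in [0, 0.5]")
        if self.tail_length < 1:
            raise ValueError("tail_length must be >= 1")


@dataclass
class PlantedGenome:
    """A synthetic genome plus its ground truth."""

    genome: dict[str, str]
    annotations: list[SINEAnnotation]
    truth: pd.DataFrame
    library: CutoffLibrary


def _hamming_divergence(a: str, b: str) -> float:
    return sum(1 for x, y in zip(a, b) if x != y) / len(a)


def plant_genome(
    specs: Sequence[PlantSpec],
    genome_len: int,
    seed: int,
    chrom: str = "chr1",
    gc: float = 0.42,
    library: Optional[CutoffLibrary] = None,
) -> PlantedGenome:
    """Plant SINE copies of known truth into a random background genome.

    Elements are placed left to right with random gaps; each element is
    ``mutate(body, d) + cutoff + tail`` (the cutoff is also mutated when
    ``cutoff_intact`` is false, with one forced substitution so the exact
    pass cannot match). The realized divergence written to the annotation is
    the Hamming divergence of the emitted element against its unmutated
    construction. Raises if the copies do not fit in ``genome_len``.
    """
    rng = np.random.default_rng(seed)
    if library is None:
        library = synthetic_default_library()

    elements = []  # (element_seq_forward, spec, truth_row_fields)
    consensus_cache: dict[str, str] = {}
    rows = []
    for spec in specs:
        motif = library.motifs_for(spec.subfamily)[0]
        if spec.consensus is not None:
            consensus_body = spec.consensus
        else:
            key = spec.subfamily
            if key not in consensus_cache:
                consensus_cache[key] = random_sequence(spec.body_length, rng, gc)
            consensus_body = consensus_cache[key]
        for _ in range(spec.copies):
            body = mutate(consensus_body, spec.divergence, rng)
            if spec.cutoff_intact:
                cutoff = motif
            else:
                cutoff = mutate(motif, max(spec.divergence, 0.1), rng)
                if cutoff == motif:  # force at least two substitutions
                    alt = "C" if motif[0] != "C" else "G"
                    alt2 = "C" if motif[1] != "C" else "G"
                    cutoff = alt + alt2 + motif[2:]
            tail = make_tail(spec.category, spec.tail_length, rng)
            element = body + cutoff + tail
            pristine = consensus_body + motif + tail
            elements.append((element, spec, pristine, tail, len(body) + len(cutoff)))

    # Place with random gaps.
    total_element_bp = sum(len(e[0]) for e in elements)
    slack = genome_len - total_element_bp
    if slack < len(elements) + 1:
        raise ValueError(
            f"{total_element_bp} bp of elements do not fit in genome of {genome_len}"
        )
    gaps = rng.multinomial(slack - len(elements) - 1, np.ones(len(elements) + 1) / (len(elements) + 1))
    gaps = gaps + 1  # every gap >= 1 bp

    pieces = []
    annotations = []
    cursor = 0
    for idx, ((element, spec, pristine, tail, tail_offset), gap) in enumerate(
        zip(elements, gaps[:-1])
    ):
        pieces.append(random_sequence(int(gap), rng, gc))
        cursor += int(gap)
        start = cursor
        end = start + len(element)
        genomic_seq = element if spec.strand == "+" else reverse_complement(element)
        pieces.append(genomic_seq)
        cursor = end
        divergence = _hamming_divergence(element, pristine)
        element_id = str(idx + 1)
        annotations.append(
            SINEAnnotation(
                interval=GenomicInterval(chrom, start, end, spec.strand),
                subfamily=spec.subfamily,
                divergence_D=divergence,
                element_id=element_id,
            )
        )
        if spec.strand == "+":
            tail_start_g, tail_end_g = start + tail_offset, end
        else:
            tail_start_g, tail_end_g = start, end - tail_offset
        rows.append(
            {
                "element_id": element_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": spec.strand,
                "subfamily": spec.subfamily,
                "tail_offset": tail_offset,
                "tail_start": tail_start_g,
                "tail_end": tail_end_g,
                "tail_seq": tail,
                "category": spec.category,
                "cutoff_intact": spec.cutoff_intact,
                "divergence": divergence,
            }
        )
    pieces.append(random_sequence(genome_len - cursor, rng, gc))
    genome_seq = "".join(pieces)

    return PlantedGenome(
        genome={chrom: genome_seq},
        annotations=annotations,
        truth=pd.DataFrame(rows),
        library=library,
    )


def write_genome_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "wt") as out:
        for chrom, seq in genome.items():
            out.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_repeatmasker_out(annotations: Iterable[SINEAnnotation], stream: Union[str, IO]) -> None:
    """Emit annotations in the RepeatMasker ``.out`` dialect (3 header lines)."""
    close = isinstance(stream, str)
    out = open(stream, "wt") if close else stream
    try:
        out.write(
            "   SW   perc perc perc  query     position in query    matching"
            "  repeat        position in repeat\n"
        )
        out.write(
            "score   div. del. ins.  sequence  begin  end   (left)  repeat"
            "  class/family  begin  end    (left)  ID\n"
        )
        out.write("\n")
        for ann in annotations:
            iv = ann.interval
            strand = "+" if iv.strand == "+" else "C"
            out.write(
                f"  225 {ann.divergence_D * 100:5.1f}  0.0  0.0  {iv.chrom} "
                f"{iv.start + 1} {iv.end} (0) {strand} {ann.subfamily} "
                f"SINE/tRNA 1 {len(iv)} (0) {ann.element_id}\n"
            )
    finally:
        if close:
            out.close()


def make_gene_models(
    truth: pd.DataFrame,
    genome_len: int,
    rng_or_seed: Union[int, np.random.Generator],
    chrom: str = "chr1",
    overlap_fraction: float = 0.5,
) -> str:
    """GFF3 text with genes whose exons/introns overlap a subset of tails.

    Every selected tail is covered by a two-exon gene whose first exon spans
    the tail (so the tail hits pcgene+exon) and whose intron lies downstream.
    Returns the GFF3 document as a string.
    """
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    lines = ["##gff-version 3"]
    n_genes = 0
    for _, row in truth.iterrows():
        if rng.random() > overlap_fraction:
            continue
        n_genes += 1
        gid, tid = f"gene{n_genes}", f"tx{n_genes}"
        exon1 = (max(0, row.tail_start - 10), min(genome_len, row.tail_end + 10))
        intron_end = min(genome_len, exon1[1] + 50)
        exon2 = (intron_end, min(genome_len, intron_end + 40))
        gene_span = (exon1[0], exon2[1])
        lines.append(
            f"{chrom}\tsynthetic\tgene\t{gene_span[0] + 1}\t{gene_span[1]}\t.\t+\t.\tID={gid}"
        )
        lines.append(
            f"{chrom}\tsynthetic\tmRNA\t{gene_span[0] + 1}\t{gene_span[1]}\t.\t+\t.\tID={tid};Parent={gid}"
        )
        for s, e in (exon1, exon2):
            lines.append(
                f"{chrom}\tsynthetic\texon\t{s + 1}\t{e}\t.\t+\t.\tParent={tid}"
            )
        lines.append(
            f"{chrom}\tsynthetic\tCDS\t{exon1[0] + 1}\t{exon1[1]}\t.\t+\t0\tParent={tid}"
        )
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class AssemblyEdit:
    """One structural edit applied to a base genome: insertion or deletion."""

    chrom: str
    position: int  # reference coordinate the edit applies at
    insert: str = ""  # inserted sequence (insertions)
    delete: int = 0  # number of reference bases removed (deletions)

    def __post_init__(self) -> None:
        if bool(self.insert) == bool(self.delete):
            raise ValueError("an edit is either an insertion or a deletion")


def make_variant_assembly(
    genome: dict[str, str],
    edits: Sequence[AssemblyEdit],
    assembly_name: str = "variant",
) -> tuple[dict[str, str], list]:
    """Apply edits to a genome and emit exact PAF records describing them.

    Edits must be non-overlapping. Returns ``(variant_genome, paf_records)``
    with one PAF record per chromosome (query = variant, target = base); with
    no edits the PAF is a pure-match identity record.
    """
    from sinetails.comparative_variation import PafAlignment

    by_chrom: dict[str, list[AssemblyEdit]] = {}
    for edit in edits:
        by_chrom.setdefault(edit.chrom, []).append(edit)
    for chrom, chrom_edits in by_chrom.items():
        chrom_edits.sort(key=lambda e: e.position)
        for a, b in zip(chrom_edits, chrom_edits[1:]):
            if a.position + a.delete > b.position:
                raise ValueError(f"overlapping edits at {chrom}:{b.position}")

    variant: dict[str, str] = {}
    paf_records = []
    for chrom, base_seq in genome.items():
        chrom_edits = by_chrom.get(chrom, [])
        pieces = []
        cigar: list[tuple[int, str]] = []
        cursor = 0
        for edit in chrom_edits:
            if edit.position > cursor:
                pieces.append(base_seq[cursor : edit.position])
                cigar.append((edit.position - cursor, "M"))
            if edit.insert:
                pieces.append(edit.insert)
                cigar.append((len(edit.insert), "I"))
                cursor = edit.position
            else:
                cigar.append((edit.delete, "D"))
                cursor = edit.position + edit.delete
        if cursor < len(base_seq):
            pieces.append(base_seq[cursor:])
            cigar.append((len(base_seq) - cursor, "M"))
        var_seq = "".join(pieces)
        variant[chrom] = var_seq
        paf_records.append(
            PafAlignment(
                query_name=chrom,
                query_length=len(var_seq),
                query_start=0,
                query_end=len(var_seq),
                strand="+",
                target_name=chrom,
                target_length=len(base_seq),
                target_start=0,
                target_end=len(base_seq),
                cigar=tuple(cigar),
            )
        )
    return variant, paf_records
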
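"""Genomic context of SINE tails: chromosome densities and feature overlaps.

A tail overlaps a feature class when they share at least one base. Class
membership is non-exclusive - a tail inside a coding exon counts in pcgene,
exon and CDS simultaneously - matching how annotation-feature totals are
usually reported. An additional single exclusive label per tail is assigned
by the priority CDS > UTR5 > UTR3 > exon > intron > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
from intervaltree import IntervalTree

from sinetails.formats_io import GeneFeatureSet

#: Feature classes, in exclusive-label priority order (intergenic last).
FEATURE_CLASSES = ("cds", "utr5", "utr3", "exon", "intron", "intergenic")
#: Classes reported in summaries (pcgene is the union of gene spans).
REPORT_CLASSES = ("pcgene", "exon", "intron", "cds", "utr5", "utr3", "intergenic")


@dataclass
class ContextSummary:
    chromosome: pd.DataFrame = field(default_factory=pd.DataFrame)
    feature_counts: pd.DataFrame = field(default_factory=pd.DataFrame)
    feature_composition: pd.DataFrame = field(default_factory=pd.DataFrame)


def _build_trees(featureset: GeneFeatureSet) -> dict[str, dict[str, IntervalTree]]:
    class_intervals = {
        "pcgene": featureset.genes,
        "exon": featureset.exons,
        "cds": featureset.cds,
        "utr5": featureset.utr5,
        "utr3": featureset.utr3,
        "intron": featureset.introns,
        "intergenic": featureset.intergenic,
    }
    trees: dict[str, dict[str, IntervalTree]] = {}
    for cls, intervals in class_intervals.items():
        per_chrom: dict[str, IntervalTree] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        trees[cls] = per_chrom
    return trees


def intersect_features(tails: Iterable, featureset: GeneFeatureSet) -> pd.DataFrame:
    """Per-tail feature-class assignments.

    Returns one row per tail with a boolean column per class (>= 1 bp overlap
    rule, non-exclusive) plus an ``exclusive`` column holding the single
    highest-priority class. Tails on chromosomes absent from the feature set
    are counted intergenic.
    """
    trees = _build_trees(featureset)
    known_chroms = set()
    for per_chrom in trees.values():
        known_chroms.update(per_chrom)
    rows = []
    for rec in tails:
        iv = rec.tail_interval
        flags = {}
        if iv.chrom not in known_chroms:
            for cls in REPORT_CLASSES:
                flags[cls] = cls == "intergenic"
        else:
            for cls in REPORT_CLASSES:
                tree = trees[cls].get(iv.chrom)
                flags[cls] = bool(tree and tree.overlap(iv.start, iv.end))
        exclusive = next(
            (cls for cls in FEATURE_CLASSES if flags[cls]), "intergenic"
        )
        rows.append(
            {
                "element_id": rec.annotation.element_id,
                "chrom": iv.chrom,
                "category": rec.category,
                **flags,
                "exclusive": exclusive,
            }
        )
    return pd.DataFrame(rows)


def chromosome_density(
    tails: Iterable, chrom_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Per-chromosome tail count and density (tails per megabase)."""
    counts: dict[str, int] = {chrom: 0 for chrom in chrom_lengths}
    for rec in tails:
        chrom = rec.tail_interval.chrom
        if chrom not in chrom_lengths:
            raise KeyError(f"no length provided for chromosome {chrom!r}")
        counts[chrom] += 1
    rows = [
        {
            "chrom": chrom,
            "length": chrom_lengths[chrom],
            "count": counts[chrom],
            "density_per_mb": counts[chrom] / (chrom_lengths[chrom] / 1e6),
        }
        for chrom in chrom_lengths
    ]
    return pd.DataFrame(rows)


def composition_by_feature(assignments: pd.DataFrame) -> pd.DataFrame:
    """Category composition within each feature class (non-exclusive counts).

    Rows are (feature_class, category) with ``count`` and ``percent``;
    percentages sum to 100 within each class; empty classes are omitted.
    """
    rows = []
    for cls in REPORT_CLASSES:
        subset = assignments[assignments[cls]]
        if subset.empty:
            continue
        counts = subset["category"].value_counts()
        for category, count in counts.items():
            rows.append(
                {
                    "feature_class": cls,
                    "category": category,
                    "count": int(count),
                    "percent": count / len(subset) * 100.0,
                }
            )
    return pd.DataFrame(rows, columns=["feature_class", "category", "count", "percent"])


def summarize_context(
    tails: list,
    featureset: GeneFeatureSet,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> ContextSummary:
    """Full context summary: densities, per-class counts, per-class composition."""
    assignments = intersect_features(tails, featureset)
    lengths = dict(chrom_lengths or featureset.chrom_lengths)
    summary = ContextSummary()
    if lengths:
        summary.chromosome = chromosome_density(tails, lengths)
    if not assignments.empty:
        summary.feature_counts = pd.DataFrame(
            {
                "feature_class": REPORT_CLASSES,
                "count": [int(assignments[cls].sum()) for cls in REPORT_CLASSES],
            }
        )
        summary.feature_composition = composition_by_feature(assignments)
    return summary
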
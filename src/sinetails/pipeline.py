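"""Pipeline orchestration: chain extraction, classification, aging, context.

Each stage logs one structured line with input/output record counts, so the
classified-versus-Other accounting can be read off any run's log.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from sinetails.age_estimation import ClockParams, DEFAULT_CLOCK, age_records, temporal_composition
from sinetails.formats_io import (
    GeneFeatureSet,
    parse_gff_features,
    parse_repeatmasker_out,
    write_tail_table,
)
from sinetails.genomic_context import summarize_context
from sinetails.tail_classification import ClassifierConfig, OTHER, classify_records
from sinetails.tail_extraction import CutoffLibrary, METHOD_FALLBACK, extract_tail

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome_path: str
    rm_out_path: str
    cutoff_lib_path: Optional[str] = None
    gff_path: Optional[str] = None
    chrom_sizes: dict = field(default_factory=dict)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    clock: ClockParams = field(default_factory=ClockParams)
    output_dir: str = "."
    fallback_length: int = 30
    max_mismatch: int = 1
    strict_other: bool = False


def _family_of(subfamily: str) -> str:
    return re.sub(r"\d+$", "", subfamily)


def run_scan(config: PipelineConfig) -> dict:
    """Run extraction -> classification -> aging -> context; write outputs.

    Returns a dict with the record list, the summary tables and the per-stage
    counts. With ``strict_other`` set, elements whose tails were produced by
    the terminal-30-bp fallback are labelled Other outright instead of being
    classified.
    """
    from pyfaidx import Fasta

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = Fasta(config.genome_path, sequence_always_upper=True)
    annotations = parse_repeatmasker_out(config.rm_out_path)
    logger.info("stage=parse annotations=%d", len(annotations))

    if config.cutoff_lib_path:
        library = CutoffLibrary.from_tsv(
            config.cutoff_lib_path, fallback_length=config.fallback_length
        )
    else:
        from sinetails.synthetic_fixtures import synthetic_default_library

        library = synthetic_default_library(fallback_length=config.fallback_length)

    records = [
        extract_tail(ann, genome, library, max_mismatch=config.max_mismatch)
        for ann in annotations
    ]
    n_fallback = sum(1 for r in records if r.method == METHOD_FALLBACK)
    logger.info("stage=extract tails=%d fallback=%d", len(records), n_fallback)

    classify_records(records, config.classifier)
    if config.strict_other:
        for rec in records:
            if rec.method == METHOD_FALLBACK:
                rec.category = OTHER
    n_other = sum(1 for r in records if r.category == OTHER)
    logger.info(
        "stage=classify records=%d classified=%d other=%d",
        len(records),
        len(records) - n_other,
        n_other,
    )

    aged, saturated = age_records(records, config.clock)
    logger.info("stage=age aged=%d saturated=%d", len(aged), len(saturated))

    write_tail_table(records, outdir / "tails.tsv")
    tables = summarize(records, clock=config.clock)

    featureset: Optional[GeneFeatureSet] = None
    if config.gff_path:
        featureset = parse_gff_features(config.gff_path, config.chrom_sizes)
        context = summarize_context(records, featureset, config.chrom_sizes)
        tables["chromosome"] = context.chromosome
        tables["feature"] = context.feature_composition
        tables["feature_counts"] = context.feature_counts
        logger.info("stage=context classes=%d", len(context.feature_counts))

    for name, table in tables.items():
        if isinstance(table, pd.DataFrame) and not table.empty:
            table.to_csv(outdir / f"summary_{name}.tsv", sep="\t", index=False)

    return {
        "records": records,
        "saturated": saturated,
        "tables": tables,
        "counts": {
            "annotations": len(annotations),
            "tails": len(records),
            "fallback": n_fallback,
            "classified": len(records) - n_other,
            "other": n_other,
            "aged": len(aged),
            "saturated": len(saturated),
        },
    }


def summarize(records: list, clock: ClockParams = DEFAULT_CLOCK) -> dict[str, pd.DataFrame]:
    """Per-grouping count/percentage tables: category, family, subfamily, bin."""
    if not records:
        return {
            name: pd.DataFrame()
            for name in ("category", "family", "subfamily", "age_bin")
        }
    df = pd.DataFrame(
        {
            "category": [r.category for r in records],
            "subfamily": [r.annotation.subfamily for r in records],
            "family": [_family_of(r.annotation.subfamily) for r in records],
            "age_bin": [r.age.bin_label if r.age else "unaged" for r in records],
        }
    )

    def table(column: str) -> pd.DataFrame:
        counts = df[column].value_counts()
        return pd.DataFrame(
            {
                column: counts.index,
                "count": counts.values,
                "percent": counts.values / len(df) * 100.0,
            }
        )

    tables = {name: table(name) for name in ("category", "family", "subfamily")}
    tables["age_bin"] = temporal_composition(records, clock)
    return tables
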
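"""Rule-based classification of SINE tails into 16 structural categories.

Tails are assigned one of 17 labels: A-rich, twelve single-motif tandem
repeat categories built from adenine plus one other base (the AT-, AC- and
AG-series motifs of length 2-5), three per-series composites, or "Other".

The decision cascade, in order:

1. **A-rich** - the longest run of consecutive A covers at least
   ``arich_min_coverage`` of the tail and is at least ``arich_min_run`` long.
2. **Composite** - at least ``composite_min_distinct`` distinct motifs of one
   series each show a tandem run of at least ``composite_min_run`` adjacent
   copies. A composite therefore reflects co-occurrence of several repeat
   units of the same series rather than one dominant run, and it is tested
   before the single-motif rules: a tail carrying, say, both (AAAC)x2 and
   (AAC)x3 is an AC-composite, not whichever single motif happens to edge
   ahead. When several series qualify, the series whose motif occurrences
   cover the most bases wins (tie broken in series order AT, AC, AG).
3. **Single motif** - among the twelve motifs whose maximal tandem run meets
   ``min_consecutive`` for its length, the hit spanning the most bases wins
   (ties: longer motif, then leftmost run).
4. **Other.**

``N`` never matches any motif and breaks A-runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

#: Series order used for composite tie-breaking.
SERIES_ORDER = ("AT", "AC", "AG")

#: The twelve AN-format motifs, grouped by series, longest first.
SERIES_MOTIFS: dict[str, tuple[str, ...]] = {
    "AT": ("AAAAT", "AAAT", "AAT", "AT"),
    "AC": ("AAAAC", "AAAC", "AAC", "AC"),
    "AG": ("AAAAG", "AAAG", "AAG", "AG"),
}

ALL_MOTIFS: tuple[str, ...] = tuple(
    motif for series in SERIES_ORDER for motif in SERIES_MOTIFS[series]
)

A_RICH = "A-rich"
OTHER = "Other"

CATEGORY_LABELS: tuple[str, ...] = (
    (A_RICH,)
    + tuple(f"({m})n" for m in ALL_MOTIFS)
    + tuple(f"{s}-composite" for s in SERIES_ORDER)
    + (OTHER,)
)


def series_of(label: str) -> str:
    """Series (AT/AC/AG/A/none) derivable from a category label."""
    if label == A_RICH:
        return "A"
    if label == OTHER:
        return "none"
    for series, motifs in SERIES_MOTIFS.items():
        if label == f"{series}-composite":
            return series
        if label in (f"({m})n" for m in motifs):
            return series
    raise ValueError(f"unknown category label {label!r}")


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the 16-category rule system.

    ``min_consecutive`` maps motif length to the minimum number of adjacent
    tandem copies a single-motif category requires: dimer repeats must appear
    at least 3 times in a row, all longer motifs at least twice. The A-rich
    rule requires a run of ``arich_min_run`` consecutive adenines covering at
    least ``arich_min_coverage`` of the tail; ``arich_total_content`` switches
    the coverage test to total A content instead of the longest run.
    """

    arich_min_run: int = 5
    arich_min_coverage: float = 0.70
    arich_total_content: bool = False
    min_consecutive: dict = field(
        default_factory=lambda: {5: 2, 4: 2, 3: 2, 2: 3}
    )
    composite_min_distinct: int = 2
    composite_min_run: int = 2

    def __post_init__(self) -> None:
        if self.arich_min_run < 1 or self.composite_min_distinct < 1:
            raise ValueError("minima must be >= 1")
        if not (0.0 < self.arich_min_coverage <= 1.0):
            raise ValueError("arich_min_coverage must be in (0, 1]")
        if any(v < 1 for v in self.min_consecutive.values()):
            raise ValueError("min_consecutive values must be >= 1")


DEFAULT_CONFIG = ClassifierConfig()


@dataclass(frozen=True)
class MotifHit:
    """Maximal tandem run of one motif: adjacent non-overlapping copies."""

    motif: str
    series: str
    max_run: int
    run_span_bp: int
    run_start: int

    def __post_init__(self) -> None:
        if self.max_run and self.run_span_bp != self.max_run * len(self.motif):
            raise ValueError("run_span_bp must equal max_run * motif length")


def longest_polyA_run(seq: str) -> tuple[int, int]:
    """Longest run of consecutive ``A`` as ``(start, length)``.

    Leftmost run on ties; ``(0, 0)`` when the sequence contains no A.
    """
    best_start, best_len = 0, 0
    run_start, run_len = 0, 0
    for i, base in enumerate(seq):
        if base == "A":
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_start, best_len = run_start, run_len
        else:
            run_len = 0
    return best_start, best_len


def max_tandem_run(seq: str, motif: str) -> MotifHit:
    """Maximum number of adjacent, non-overlapping copies of ``motif``.

    Any starting phase is considered; the leftmost maximal run wins ties.
    ``max_run`` is 0 when the motif never occurs.
    """
    m = len(motif)
    series = next(
        (s for s, motifs in SERIES_MOTIFS.items() if motif in motifs), "none"
    )
    best_run, best_start = 0, 0
    i = 0
    n = len(seq)
    while i + m <= n:
        if seq[i : i + m] == motif:
            run = 1
            j = i + m
            while j + m <= n and seq[j : j + m] == motif:
                run += 1
                j += m
            if run > best_run:
                best_run, best_start = run, i
            i += 1  # a longer run in a different phase may start inside this one
        else:
            i += 1
    return MotifHit(
        motif=motif,
        series=series,
        max_run=best_run,
        run_span_bp=best_run * m,
        run_start=best_start if best_run else 0,
    )


def _series_coverage(seq: str, series: str) -> int:
    """Bases of ``seq`` covered by any occurrence of the series' motifs."""
    covered = bytearray(len(seq))
    for motif in SERIES_MOTIFS[series]:
        m = len(motif)
        start = seq.find(motif)
        while start != -1:
            for k in range(start, start + m):
                covered[k] = 1
            start = seq.find(motif, start + 1)
    return sum(covered)


def classify_tail(seq: str, config: ClassifierConfig = DEFAULT_CONFIG) -> str:
    """Assign one of the 17 category labels to a tail sequence.

    Total and deterministic: every sequence (including the empty one, which
    is Other) maps to exactly one label.
    """
    seq = seq.upper()
    if not seq:
        return OTHER

    # 1. A-rich.
    _, run_len = longest_polyA_run(seq)
    a_measure = seq.count("A") if config.arich_total_content else run_len
    if run_len >= config.arich_min_run and a_measure / len(seq) >= config.arich_min_coverage:
        return A_RICH

    hits = {motif: max_tandem_run(seq, motif) for motif in ALL_MOTIFS}

    # 2. Composite: >= composite_min_distinct motifs of one series, each with
    # a tandem run of >= composite_min_run adjacent copies.
    qualifying_series = []
    for series in SERIES_ORDER:
        distinct = [
            m
            for m in SERIES_MOTIFS[series]
            if hits[m].max_run >= config.composite_min_run
        ]
        if len(distinct) >= config.composite_min_distinct:
            qualifying_series.append(series)
    if qualifying_series:
        best = max(
            qualifying_series,
            key=lambda s: (_series_coverage(seq, s), -SERIES_ORDER.index(s)),
        )
        return f"{best}-composite"

    # 3. Single motif: largest tandem span among qualifying motifs.
    qualifying = [
        hit
        for motif, hit in hits.items()
        if hit.max_run >= config.min_consecutive[len(motif)]
    ]
    if qualifying:
        best_hit = max(
            qualifying,
            key=lambda h: (h.run_span_bp, len(h.motif), -h.run_start),
        )
        return f"({best_hit.motif})n"

    return OTHER


def classify_records(records: Iterable, config: ClassifierConfig = DEFAULT_CONFIG) -> list:
    """Assign categories to TailRecords in place; returns the list."""
    records = list(records)
    for rec in records:
        rec.category = classify_tail(rec.tail_seq, config)
    return records


def tail_composition_stats(records: Iterable) -> dict:
    """Summary statistics over classified tails.

    Returns per-category counts and proportions, plus descriptive statistics
    of the "Other" class: mean/sd tail length, mean/sd adenine fraction, the
    fraction with sub-threshold (50-70%) A content, and the fraction carrying
    any AN-format motif tandem run of >= 2 copies.
    """
    records = list(records)
    if not records:
        raise ValueError("tail_composition_stats requires at least one record")
    categories = pd.Series([rec.category for rec in records])
    counts = categories.value_counts()
    summary = pd.DataFrame(
        {"count": counts, "proportion": counts / len(records)}
    ).rename_axis("category")

    others = [rec.tail_seq for rec in records if rec.category == OTHER]
    other_stats = {}
    if others:
        lengths = pd.Series([len(s) for s in others], dtype=float)
        a_frac = pd.Series(
            [s.count("A") / len(s) if s else 0.0 for s in others], dtype=float
        )
        sub_threshold = ((a_frac >= 0.5) & (a_frac < 0.7)).mean()
        any_run2 = sum(
            1
            for s in others
            if any(max_tandem_run(s.upper(), m).max_run >= 2 for m in ALL_MOTIFS)
        ) / len(others)
        other_stats = {
            "mean_length": lengths.mean(),
            "sd_length": lengths.std(ddof=0),
            "mean_a_fraction": a_frac.mean(),
            "sd_a_fraction": a_frac.std(ddof=0),
            "frac_a_content_50_70": float(sub_threshold),
            "frac_subthreshold_motif_run": any_run2,
        }
    return {"by_category": summary, "other": other_stats}
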
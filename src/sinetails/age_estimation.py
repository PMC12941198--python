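"""Jukes-Cantor insertion-age estimation and 5-My temporal binning.

Each element's proportional divergence D from its subfamily consensus (as
reported by the annotation, computed over the complete element including the
tail) is corrected for multiple substitutions with the Jukes-Cantor distance
K = -0.75 * ln(1 - 4D/3) and converted to absolute time with a neutral
molecular clock. The default conversion is age = K / (2 * mu) with the pig
neutral substitution rate mu = 2.3e-9 per site per year; the more common
transposable-element convention age = K / mu is available as a switch. Ages
are binned into half-open 5-My intervals [L, L+5) from 0 to 85 My; ages of
85 My and beyond go to an overflow bin excluded from composition tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

JC_SATURATION = 0.75


class SaturatedDivergenceError(ValueError):
    """Divergence at or beyond the Jukes-Cantor saturation point (D >= 0.75)."""


@dataclass(frozen=True)
class ClockParams:
    """Molecular clock and binning parameters."""

    mu: float = 2.3e-9  # substitutions / site / year
    bin_width_my: int = 5
    max_bin_my: int = 85
    age_formula: str = "k-over-2mu"  # or "k-over-mu"

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.max_bin_my % self.bin_width_my != 0:
            raise ValueError("bin_width_my must divide max_bin_my")
        if self.age_formula not in ("k-over-2mu", "k-over-mu"):
            raise ValueError(f"unknown age_formula {self.age_formula!r}")


DEFAULT_CLOCK = ClockParams()

OVERFLOW_BIN = "85+"


@dataclass(frozen=True)
class AgeEstimate:
    divergence_D: float
    K: float
    age_my: float
    bin_label: str


def jc_distance(D: float) -> float:
    """Jukes-Cantor distance K = -0.75 * ln(1 - 4D/3).

    Strictly increasing in D, zero iff D is zero; raises
    :class:`SaturatedDivergenceError` at or beyond D = 0.75, where the
    correction diverges and the element cannot be dated.
    """
    if D < 0:
        raise ValueError(f"divergence must be >= 0, got {D}")
    if D >= JC_SATURATION:
        raise SaturatedDivergenceError(
            f"divergence {D} is at or beyond Jukes-Cantor saturation (0.75)"
        )
    return -0.75 * math.log(1.0 - 4.0 * D / 3.0)


def age_from_K(K: float, clock: ClockParams = DEFAULT_CLOCK) -> float:
    """Absolute age in million years from a Jukes-Cantor distance."""
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    divisor = 2.0 * clock.mu if clock.age_formula == "k-over-2mu" else clock.mu
    return K / divisor / 1e6


def bin_age(age_my: float, clock: ClockParams = DEFAULT_CLOCK) -> str:
    """Half-open bin label "L-U" with U = L + bin width; ">= max" overflows."""
    if age_my < 0:
        raise ValueError(f"age must be >= 0, got {age_my}")
    if age_my >= clock.max_bin_my:
        return f"{clock.max_bin_my}+"
    low = clock.bin_width_my * int(age_my // clock.bin_width_my)
    return f"{low}-{low + clock.bin_width_my}"


def estimate_age(divergence_D: float, clock: ClockParams = DEFAULT_CLOCK) -> AgeEstimate:
    """Full divergence -> K -> age -> bin conversion for one element."""
    K = jc_distance(divergence_D)
    age = age_from_K(K, clock)
    return AgeEstimate(
        divergence_D=divergence_D, K=K, age_my=age, bin_label=bin_age(age, clock)
    )


def age_records(records: Iterable, clock: ClockParams = DEFAULT_CLOCK) -> tuple[list, list]:
    """Attach AgeEstimates to TailRecords.

    Returns ``(aged, saturated)``: elements at or beyond Jukes-Cantor
    saturation are excluded from aging and returned separately with
    ``age = None``.
    """
    aged, saturated = [], []
    for rec in records:
        try:
            rec.age = estimate_age(rec.annotation.divergence_D, clock)
            aged.append(rec)
        except SaturatedDivergenceError:
            rec.age = None
            saturated.append(rec)
    return aged, saturated


def temporal_composition(records: Iterable, clock: ClockParams = DEFAULT_CLOCK) -> pd.DataFrame:
    """Per-bin category counts and within-bin percentages.

    Rows are (bin, category) with columns ``count`` and ``percent``; bins with
    no records are omitted, the overflow bin is excluded, and percentages sum
    to 100 within each bin.
    """
    rows = [
        (rec.age.bin_label, rec.category)
        for rec in records
        if rec.age is not None and rec.age.bin_label != f"{clock.max_bin_my}+"
    ]
    if not rows:
        return pd.DataFrame(columns=["bin", "category", "count", "percent"])
    df = pd.DataFrame(rows, columns=["bin", "category"])
    counts = df.groupby(["bin", "category"], sort=False).size().rename("count").reset_index()
    totals = counts.groupby("bin")["count"].transform("sum")
    counts["percent"] = counts["count"] / totals * 100.0
    counts["_low"] = counts["bin"].str.split("-").str[0].astype(int)
    counts = counts.sort_values(["_low", "category"]).drop(columns="_low")
    return counts.reset_index(drop=True)
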
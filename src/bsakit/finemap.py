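"""Recombinant-count fine mapping within a candidate interval.

Every individual in the screen has the mutant phenotype, so at the causal
locus all of them are homozygous mutant. A marker call of 0 (homozygous
wild type) or 1 (heterozygous) therefore witnesses a crossover between the
marker and the locus; markers flanking a run of zero-recombinant markers
bound the locus. Missing calls are excluded, never counted as recombinant.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "RecombinantCount",
    "RefinedInterval",
    "count_recombinants",
    "refine_interval",
    "interval_width_kb",
    "RecombinantScreen",
    "FineMapResults",
]


@dataclass(frozen=True)
class RecombinantCount:
    marker: str
    n_recombinant: int
    n_informative: int
    recombinant_ids: tuple[str, ...]


@dataclass(frozen=True)
class RefinedInterval:
    """Interval bounded by the nearest recombinant-bearing flanking markers.

    Endpoints are the flanking markers' own positions, inclusive. An open
    flag on a side means the zero-recombinant run reached the outermost
    genotyped marker there, so that side is unbounded by the data.
    """

    chrom: str
    left_marker: str | None
    right_marker: str | None
    start: int
    end: int
    open_left: bool
    open_right: bool
    counts: dict[str, int]

    @property
    def width_kb(self) -> int | None:
        """Width in kb (half-up integer); None when a side is open."""
        if self.open_left or self.open_right:
            return None
        return interval_width_kb(self.start, self.end)

    def __str__(self) -> str:
        left = "(open)" if self.open_left else self.left_marker
        right = "(open)" if self.open_right else self.right_marker
        w = "" if self.width_kb is None else f", {self.width_kb} kb"
        return f"{self.chrom}:{self.start}-{self.end} [{left}..{right}{w}]"


def interval_width_kb(start: int, end: int) -> int:
    """Width of [start, end] in kb, rounded half-up to an integer."""
    if start >= end:
        raise ValueError(f"start {start} must be < end {end}")
    return int(
        Decimal(end - start).scaleb(-3).quantize(0, rounding=ROUND_HALF_UP)
    )


def count_recombinants(
    matrix: pd.DataFrame, marker: str
) -> RecombinantCount:
    """Count recombinants at one marker among mutant-phenotype individuals.

    Recombinant = call 0 or 1 (any non-homozygous-mutant call). Missing
    calls drop out of both numerator and denominator.
    """
    if marker not in matrix.columns:
        raise KeyError(f"unknown marker {marker!r}")
    col = matrix[marker]
    informative = col.notna()
    rec = informative & (col != 2)
    return RecombinantCount(
        marker=marker,
        n_recombinant=int(rec.sum()),
        n_informative=int(informative.sum()),
        recombinant_ids=tuple(str(i) for i in matrix.index[rec]),
    )


def refine_interval(
    matrix: pd.DataFrame, markers: pd.DataFrame
) -> RefinedInterval:
    """Bound the locus by the flanking recombinant-bearing markers.

    ``markers`` has columns ``id, chrom, pos`` (one chromosome,
    coordinate-ordered; unordered input is sorted). The longest run of
    markers with zero recombinants is located (ties: leftmost) and the
    interval spans from the nearest marker with >= 1 recombinant on its
    left to the nearest such marker on its right. A run touching the
    outermost marker leaves that side open-ended.
    """
    if len(markers) < 2:
        raise ValueError("need at least two ordered markers")
    chroms = set(markers["chrom"])
    if len(chroms) != 1:
        raise ValueError(f"markers span multiple chromosomes: {sorted(chroms)}")
    ordered = markers.sort_values("pos", kind="stable").reset_index(drop=True)
    counts = [count_recombinants(matrix, m) for m in ordered["id"]]
    n_rec = np.array([c.n_recombinant for c in counts])

    zero = n_rec == 0
    if not zero.any():
        raise ValueError(
            "locus not contained: every marker shows recombinants"
        )
    # longest zero-recombinant run, leftmost on ties
    best_start = best_len = -1
    i = 0
    while i < len(zero):
        if zero[i]:
            j = i
            while j + 1 < len(zero) and zero[j + 1]:
                j += 1
            if j - i + 1 > best_len:
                best_start, best_len = i, j - i + 1
            i = j + 1
        else:
            i += 1
    lo, hi = best_start, best_start + best_len - 1

    open_left = lo == 0
    open_right = hi == len(ordered) - 1
    left_i = lo if open_left else lo - 1
    right_i = hi if open_right else hi + 1
    return RefinedInterval(
        chrom=str(ordered.loc[0, "chrom"]),
        left_marker=None if open_left else str(ordered.loc[left_i, "id"]),
        right_marker=None if open_right else str(ordered.loc[right_i, "id"]),
        start=int(ordered.loc[left_i, "pos"]),
        end=int(ordered.loc[right_i, "pos"]),
        open_left=open_left,
        open_right=open_right,
        counts={c.marker: c.n_recombinant for c in counts},
    )


class RecombinantScreen:
    """Fine-mapping screen: genotype matrix + marker map -> refined interval.

    Parameters
    ----------
    genotypes
        Individuals x markers matrix of {0,1,2,NaN} calls; all individuals
        must be of the mutant phenotype class.
    markers
        Marker table with ``id, chrom, pos`` for every matrix column used.
    """

    def __init__(self, genotypes: pd.DataFrame, markers: pd.DataFrame) -> None:
        unknown = set(markers["id"]) - set(genotypes.columns)
        if unknown:
            raise KeyError(f"markers absent from the matrix: {sorted(unknown)}")
        self.genotypes = genotypes
        self.markers = markers

    def fit(self) -> "FineMapResults":
        ordered = self.markers.sort_values("pos", kind="stable").reset_index(
            drop=True
        )
        counts = [
            count_recombinants(self.genotypes, m) for m in ordered["id"]
        ]
        interval = refine_interval(self.genotypes, ordered)
        table = pd.DataFrame(
            {
                "marker": ordered["id"],
                "chrom": ordered["chrom"],
                "pos": ordered["pos"],
                "n_recombinant": [c.n_recombinant for c in counts],
                "n_informative": [c.n_informative for c in counts],
            }
        )
        return FineMapResults(
            table=table, interval=interval, n_individuals=len(self.genotypes)
        )


@dataclass
class FineMapResults:
    table: pd.DataFrame
    interval: RefinedInterval
    n_individuals: int

    def summary(self) -> str:
        lines = [
            "Recombinant-count fine mapping",
            "==============================",
            f"individuals (mutant class): {self.n_individuals}",
            self.table.to_string(index=False),
            f"refined interval: {self.interval}",
        ]
        return "\n".join(lines)

    def to_bed(self) -> pd.DataFrame:
        iv = self.interval
        return pd.DataFrame(
            [
                {
                    "chrom": iv.chrom,
                    "start": iv.start - 1,
                    "end": iv.end,
                    "name": "refined_interval",
                }
            ]
        )
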
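"""SNP-index bulked-segregant mapping.

For every biallelic site covered in both phenotype pools the SNP-index is
the fraction of reads carrying the mutant allele,

    SNP-index = alt reads / total reads            (per pool)
    dSNP-index = SNP-index(MP) - SNP-index(WP),

and candidate regions are maximal runs of consecutive sites whose chosen
statistic clears a threshold (default: mutant-pool SNP-index >= 0.9). For
a recessive causal site the mutant-pool index is expected to be 1 and the
wild-type-pool index 1/3, so the delta statistic has expectation 2/3 and
is offered as an alternative, not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import io as _io

__all__ = [
    "MappingConfig",
    "CandidateInterval",
    "compute_snp_index",
    "window_profile",
    "call_intervals",
    "BsaScan",
    "BsaScanResults",
]


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MappingConfig:
    """Tuning knobs of the scan.

    threshold: statistic cut-off for interval calling (default 0.9).
    statistic: "mp" (mutant-pool SNP-index) or "delta" (MP - WP).
    min_depth: per-pool depth below which a site is filtered out.
    gap_tolerance: sub-threshold sites tolerated inside a run.
    window_span/window_step/min_sites: optional sliding-window smoothing
    (off when window_span is None; per-site values are used directly).
    """

    threshold: float = 0.9
    statistic: str = "mp"
    min_depth: int = 10
    gap_tolerance: int = 0
    window_span: int | None = None
    window_step: int | None = None
    min_sites: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if self.statistic not in ("mp", "delta"):
            raise ValueError("statistic must be 'mp' or 'delta'")
        if self.min_depth < 0 or self.gap_tolerance < 0 or self.min_sites < 1:
            raise ValueError("negative filter parameter")
        if self.window_span is not None:
            step = self.window_step or self.window_span
            if step > self.window_span:
                raise ValueError("window step must not exceed span")

    @property
    def statistic_column(self) -> str:
        return {"mp": "mp_index", "delta": "delta"}[self.statistic]


@dataclass(frozen=True)
class CandidateInterval:
    """A contiguous above-threshold region."""

    chrom: str
    start: int  # bp, 1-based inclusive
    end: int
    peak_value: float
    n_sites: int

    @property
    def width_bp(self) -> int:
        return self.end - self.start

    @property
    def width_mb(self) -> float:
        """Width in Mb, rounded half-up to two decimals."""
        return _round_half_up(self.width_bp / 1e6, 2)

    def __str__(self) -> str:
        return (
            f"{self.chrom}:{self.start}-{self.end} "
            f"({self.width_mb:.2f} Mb, peak {self.peak_value:.3f}, "
            f"{self.n_sites} sites)"
        )


def compute_snp_index(
    counts: pd.DataFrame, config: MappingConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site SNP-index records and the sites filtered out.

    Returns ``(records, filtered)``: records carry ``wp_index``,
    ``mp_index`` and ``delta`` columns; filtered carries a ``reason``
    column ("zero depth" or "depth < min_depth"). Indices are plain
    alt/total ratios with no intermediate rounding.
    """
    config = config or MappingConfig()
    df = counts.sort_values(["chrom", "pos"], kind="stable").reset_index(
        drop=True
    )
    bad = (df["wp_alt"] > df["wp_dp"]) | (df["mp_alt"] > df["mp_dp"])
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"alt exceeds depth at {df.loc[i, 'chrom']}:{df.loc[i, 'pos']}"
        )
    zero = (df["wp_dp"] == 0) | (df["mp_dp"] == 0)
    shallow = ~zero & (
        (df["wp_dp"] < config.min_depth) | (df["mp_dp"] < config.min_depth)
    )
    reason = np.where(zero, "zero depth", f"depth < {config.min_depth}")
    filtered = df[zero | shallow].copy()
    filtered["reason"] = reason[zero | shallow]
    records = df[~(zero | shallow)].copy()
    records["wp_index"] = records["wp_alt"] / records["wp_dp"]
    records["mp_index"] = records["mp_alt"] / records["mp_dp"]
    records["delta"] = records["mp_index"] - records["wp_index"]
    return records.reset_index(drop=True), filtered.reset_index(drop=True)


def window_profile(
    records: pd.DataFrame, config: MappingConfig
) -> pd.DataFrame:
    """Sliding-window means of the chosen statistic along each chromosome.

    Windows span ``window_span`` bp advancing by ``window_step``; the mean
    is unweighted over the sites inside the window, and windows with fewer
    than ``min_sites`` sites are flagged unsupported (mean NaN).
    """
    if config.window_span is None:
        raise ValueError("window_span is not set in the config")
    span = config.window_span
    step = config.window_step or span
    col = config.statistic_column
    out = []
    for chrom, sub in records.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        vals = sub[col].to_numpy()
        last = int(pos.max())
        start = 1
        while start <= last:
            end = start + span - 1
            inside = (pos >= start) & (pos <= end)
            n = int(inside.sum())
            supported = n >= config.min_sites
            out.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "midpoint": (start + end) // 2,
                    "mean": float(vals[inside].mean()) if supported else np.nan,
                    "n_sites": n,
                    "supported": supported,
                }
            )
            start += step
    return pd.DataFrame(out)


def call_intervals(
    records: pd.DataFrame, config: MappingConfig | None = None
) -> list[CandidateInterval]:
    """Merge threshold-clearing runs of sites into candidate intervals.

    Input is either per-site records (from :func:`compute_snp_index`) or a
    window profile (``midpoint``/``mean`` columns); positions must be
    sorted within chromosomes. Runs may bridge up to ``gap_tolerance``
    consecutive sub-threshold sites. Intervals are returned widest first
    (ties: leftmost).
    """
    config = config or MappingConfig()
    if records.empty:
        return []
    if "midpoint" in records.columns:  # window profile
        work = records[records["supported"]].rename(
            columns={"midpoint": "pos", "mean": "_stat"}
        )[["chrom", "pos", "_stat"]]
    else:
        work = records[["chrom", "pos", config.statistic_column]].rename(
            columns={config.statistic_column: "_stat"}
        )
    intervals: list[CandidateInterval] = []
    for chrom, sub in work.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        stat = sub["_stat"].to_numpy()
        passing = np.flatnonzero(stat >= config.threshold)
        if len(passing) == 0:
            continue
        run = [passing[0]]
        for j in passing[1:]:
            if j - run[-1] - 1 <= config.gap_tolerance:
                run.append(j)
            else:
                intervals.append(_make_interval(chrom, pos, stat, run))
                run = [j]
        intervals.append(_make_interval(chrom, pos, stat, run))
    intervals.sort(key=lambda iv: (-iv.width_bp, iv.chrom, iv.start))
    return intervals


def _make_interval(chrom, pos, stat, run) -> CandidateInterval:
    idx = np.asarray(run)
    return CandidateInterval(
        chrom=str(chrom),
        start=int(pos[idx[0]]),
        end=int(pos[idx[-1]]),
        peak_value=float(stat[idx].max()),
        n_sites=len(idx),
    )


class BsaScan:
    """SNP-index scan over pooled allele counts.

    Parameters
    ----------
    counts
        Per-site pooled counts (``chrom, pos, ref, alt, wp_alt, wp_dp,
        mp_alt, mp_dp``), e.g. from :func:`bsakit.io.read_pooled_vcf` or
        the simulator.
    config
        :class:`MappingConfig`; defaults apply an MP SNP-index >= 0.9 rule
        with a 10x per-pool depth filter.
    """

    def __init__(
        self, counts: pd.DataFrame, config: MappingConfig | None = None
    ) -> None:
        self.counts = counts
        self.config = config or MappingConfig()

    @classmethod
    def from_vcf(
        cls, path, config: MappingConfig | None = None, **kwargs
    ) -> "BsaScan":
        return cls(_io.read_pooled_vcf(path, **kwargs), config)

    @classmethod
    def from_tsv(cls, path, config: MappingConfig | None = None) -> "BsaScan":
        return cls(_io.read_counts_tsv(path), config)

    def fit(self) -> "BsaScanResults":
        records, filtered = compute_snp_index(self.counts, self.config)
        profile = None
        if self.config.window_span is not None:
            profile = window_profile(records, self.config)
            intervals = call_intervals(profile, self.config)
        else:
            intervals = call_intervals(records, self.config)
        return BsaScanResults(
            records=records,
            filtered=filtered,
            intervals=intervals,
            profile=profile,
            config=self.config,
        )


@dataclass
class BsaScanResults:
    """Outcome of a :class:`BsaScan` fit."""

    records: pd.DataFrame
    filtered: pd.DataFrame
    intervals: list[CandidateInterval]
    config: MappingConfig
    profile: pd.DataFrame | None = None

    @property
    def top_interval(self) -> CandidateInterval | None:
        return self.intervals[0] if self.intervals else None

    def summary(self) -> str:
        lines = [
            "SNP-index bulked-segregant scan",
            "===============================",
            f"statistic: {self.config.statistic}  "
            f"threshold: {self.config.threshold}  "
            f"min depth/pool: {self.config.min_depth}",
            f"sites used: {len(self.records)}  "
            f"filtered: {len(self.filtered)}",
            f"candidate intervals: {len(self.intervals)}",
        ]
        for iv in self.intervals[:10]:
            lines.append(f"  {iv}")
        return "\n".join(lines)

    def to_bed(self) -> pd.DataFrame:
        """Intervals as 0-based half-open BED records."""
        return pd.DataFrame(
            [
                {
                    "chrom": iv.chrom,
                    "start": iv.start - 1,
                    "end": iv.end,
                    "name": f"interval_{i + 1}",
                    "score": iv.peak_value,
                }
                for i, iv in enumerate(self.intervals)
            ]
        )

    def plot(self, ax=None):
        """Per-site statistic along the genome with the threshold line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        col = self.config.statistic_column
        offset = 0
        ticks, labels = [], []
        for chrom, sub in self.records.groupby("chrom", sort=False):
            x = sub["pos"].to_numpy() + offset
            ax.scatter(x, sub[col], s=4)
            ticks.append(offset + sub["pos"].max() / 2)
            labels.append(str(chrom))
            offset += int(sub["pos"].max())
        ax.axhline(self.config.threshold, ls=":", color="k")
        ax.set_xticks(ticks, labels)
        ax.set_ylabel(
            "MP SNP-index" if self.config.statistic == "mp" else "dSNP-index"
        )
        ax.set_ylim(-1.05 if self.config.statistic == "delta" else 0, 1.05)
        return ax
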
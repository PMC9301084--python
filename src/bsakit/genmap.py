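"""Genetic maps: physical (bp) and genetic (cM) coordinates per chromosome.

A :class:`GeneticMap` is a piecewise-linear relation between physical position
(1-based bp, VCF convention) and genetic position (cM) on each chromosome.
Every chromosome has implicit anchors at ``(1 bp, 0 cM)`` and
``(length_bp, length_cm)``; optional interior anchors let the relation bend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Chromosome", "GeneticMap"]


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: name, physical length in bp, genetic length in cM."""

    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"chromosome {self.name}: length_bp must be >= 1")
        if self.length_cm < 0:
            raise ValueError(f"chromosome {self.name}: length_cm must be >= 0")


@dataclass
class GeneticMap:
    """Piecewise-linear bp <-> cM map over one or more chromosomes.

    Parameters
    ----------
    chromosomes
        At least one :class:`Chromosome`.
    anchors
        Optional interior anchor points ``(chromosome name, bp, cM)``.
        Genetic positions must be non-decreasing in physical position.
    """

    chromosomes: list[Chromosome]
    anchors: list[tuple[str, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("a GeneticMap needs at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        self._by_name = {c.name: c for c in self.chromosomes}
        # per-chromosome sorted anchor arrays, ends included
        self._grid: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in self.chromosomes:
            pts = [(1, 0.0), (chrom.length_bp, chrom.length_cm)]
            for name, bp, cm in self.anchors:
                if name != chrom.name:
                    continue
                if not 1 <= bp <= chrom.length_bp:
                    raise ValueError(
                        f"anchor at {name}:{bp} outside chromosome length"
                    )
                pts.append((int(bp), float(cm)))
            pts.sort()
            bps = np.array([p[0] for p in pts], dtype=float)
            cms = np.array([p[1] for p in pts], dtype=float)
            if np.any(np.diff(cms) < 0):
                raise ValueError(
                    f"genetic positions decrease with bp on {chrom.name}"
                )
            if np.any(cms < 0) or np.any(cms > chrom.length_cm):
                raise ValueError(
                    f"anchor cM outside [0, {chrom.length_cm}] on {chrom.name}"
                )
            self._grid[chrom.name] = (bps, cms)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def chromosome(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def bp_to_cm(self, name: str, bp) -> np.ndarray | float:
        """Interpolate genetic position (cM) at physical position(s) bp."""
        bps, cms = self._grid[name]
        out = np.interp(np.asarray(bp, dtype=float), bps, cms)
        return float(out) if np.ndim(bp) == 0 else out

    def cm_to_bp(self, name: str, cm) -> np.ndarray | float:
        """Interpolate physical position (bp) at genetic position(s) cM.

        On flat segments (zero recombination over a physical stretch) the
        leftmost bp of the segment is returned.
        """
        bps, cms = self._grid[name]
        out = np.interp(np.asarray(cm, dtype=float), cms, bps)
        return float(out) if np.ndim(cm) == 0 else out

    @classmethod
    def maize_like(cls) -> "GeneticMap":
        """A 10-chromosome map with maize-scale physical and genetic lengths.

        Lengths approximate the B73 reference assembly (bp, rounded to Mb)
        and typical per-chromosome genetic lengths summing to roughly
        1500 cM. Recombination is uniform within each chromosome.
        """
        sizes_mb = [307, 244, 235, 246, 223, 173, 182, 181, 159, 150]
        cm = [200, 170, 160, 165, 155, 130, 140, 140, 125, 115]
        return cls(
            [
                Chromosome(f"chr{i + 1}", mb * 1_000_000, c)
                for i, (mb, c) in enumerate(zip(sizes_mb, cm))
            ]
        )

    @classmethod
    def demo(cls) -> "GeneticMap":
        """A small 3-chromosome map for quick examples and tests."""
        return cls(
            [
                Chromosome("chr1", 50_000_000, 80.0),
                Chromosome("chr2", 40_000_000, 60.0),
                Chromosome("chr3", 30_000_000, 50.0),
            ]
        )
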
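"""Readers and writers for the pipeline's file formats.

Pooled allele counts travel either as a minimal two-sample VCF 4.2 (one
sample column per pool, AD and DP FORMAT fields; everything else ignored)
or as a flat TSV. Fine-mapping genotype calls travel as a TSV matrix of
{0,1,2,NA} with individuals in rows and markers in columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "wp_alt", "wp_dp", "mp_alt", "mp_dp"]

__all__ = [
    "PooledSiteCounts",
    "read_pooled_vcf",
    "write_pooled_vcf",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_marker_table",
]


@dataclass(frozen=True)
class PooledSiteCounts:
    """Alt and total read counts for one biallelic site in both pools."""

    chrom: str
    pos: int
    ref: str
    alt: str
    wp_alt: int
    wp_dp: int
    mp_alt: int
    mp_dp: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("position must be 1-based (>= 1)")
        for a, t in ((self.wp_alt, self.wp_dp), (self.mp_alt, self.mp_dp)):
            if not 0 <= a <= t:
                raise ValueError(f"alt count {a} outside [0, {t}]")


def write_pooled_vcf(
    counts: pd.DataFrame,
    path: str | Path,
    *,
    contigs: dict[str, int] | None = None,
    wp_sample: str = "WP",
    mp_sample: str = "MP",
) -> None:
    """Write pooled counts as a minimal VCF 4.2 with AD/DP per pool sample.

    AD is emitted as ``ref,alt`` with ref = DP - alt; genotypes are not
    called (GT omitted — only the allelic depths matter downstream).
    """
    counts = counts.sort_values(["chrom", "pos"], kind="stable")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsakit\n")
        if contigs is None:
            contigs = {
                c: int(counts.loc[counts["chrom"] == c, "pos"].max())
                for c in counts["chrom"].unique()
            }
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">\n'
        )
        fh.write(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{wp_sample}\t{mp_sample}\n"
        )
        for row in counts.itertuples(index=False):
            wp = f"{row.wp_dp - row.wp_alt},{row.wp_alt}:{row.wp_dp}"
            mp = f"{row.mp_dp - row.mp_alt},{row.mp_alt}:{row.mp_dp}"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\t"
                f"AD:DP\t{wp}\t{mp}\n"
            )


def read_pooled_vcf(
    path: str | Path,
    *,
    wp_sample: str | None = None,
    mp_sample: str | None = None,
) -> pd.DataFrame:
    """Read pooled per-site counts from a two-pool VCF.

    Biallelic SNPs are returned in coordinate order; multi-allelic records
    and indels are skipped (count logged). Sample columns default to the
    first (wild-type pool) and second (mutant pool) samples. Raises if a
    sample lacks the AD FORMAT field or the file is coordinate-unsorted.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) < 2:
        raise ValueError(
            f"expected two pool sample columns, found {samples or 'none'}"
        )
    wp_sample = wp_sample or samples[0]
    mp_sample = mp_sample or samples[1]
    for s in (wp_sample, mp_sample):
        if s not in samples:
            raise ValueError(f"sample {s!r} not present in {path}")
    iw, im = samples.index(wp_sample), samples.index(mp_sample)

    rows = []
    skipped = 0
    last: tuple | None = None
    seen_chroms: set[str] = set()
    for v in vcf:
        if last is not None and v.CHROM == last[0] and v.POS < last[1]:
            raise ValueError(
                f"unsorted input at {v.CHROM}:{v.POS} (after {last[1]})"
            )
        if v.CHROM != (last[0] if last else None):
            if v.CHROM in seen_chroms:
                raise ValueError(
                    f"unsorted input: chromosome {v.CHROM} appears twice"
                )
            seen_chroms.add(v.CHROM)
        last = (v.CHROM, v.POS)
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ValueError(
                f"record {v.CHROM}:{v.POS} lacks the AD FORMAT field for "
                f"samples {wp_sample!r}/{mp_sample!r}"
            )
        ad = np.asarray(ad)
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        totals = (
            np.asarray(dp).reshape(-1)
            if dp is not None
            else ad.clip(min=0).sum(axis=1)
        )
        rows.append(
            (
                v.CHROM,
                v.POS,
                v.REF,
                v.ALT[0],
                int(max(ad[iw, 1], 0)),
                int(max(totals[iw], 0)),
                int(max(ad[im, 1], 0)),
                int(max(totals[im], 0)),
            )
        )
    if skipped:
        logger.info("skipped %d multi-allelic/indel records", skipped)
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    df.attrs["skipped_records"] = skipped
    return df


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts TSV missing columns {sorted(missing)}")
    return df


def write_genotype_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write an individuals x markers matrix of {0,1,2,NA} calls."""
    matrix.astype("Int64").to_csv(
        path, sep="\t", index=True, index_label="individual", na_rep="NA"
    )


def read_genotype_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genotype matrix TSV: rows individuals, columns markers.

    Cells must be 0, 1, 2 or NA; missing calls stay missing (NaN), never
    imputed. Out-of-alphabet cells raise with their row/column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        for ind, raw in df[col].items():
            val = (raw or "").strip() if isinstance(raw, str) else raw
            if val in ("NA", "", None) or (
                isinstance(val, float) and np.isnan(val)
            ):
                out.loc[ind, col] = np.nan
            elif val in ("0", "1", "2"):
                out.loc[ind, col] = int(val)
            else:
                raise ValueError(
                    f"invalid genotype call {raw!r} at individual {ind!r}, "
                    f"marker {col!r} (expected 0/1/2/NA)"
                )
    return out


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Read a marker description TSV with columns ``id, chrom, pos``."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    missing = {"id", "chrom", "pos"} - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns {sorted(missing)}")
    return df
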
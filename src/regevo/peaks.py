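"""Consensus peak building from replicate ChIP-seq peak calls.

A peak is *reproducible* when it overlaps peaks from enough other biological
replicates, each overlap covering at least ``min_overlap`` of the shorter of
the two peaks.  Reproducible peaks connected by qualifying overlaps are merged
(transitively, across all replicates) into one consensus region.  Species
profiled with a single replicate can keep all their peaks via
``single_replicate_ok`` — the consensus then equals the input verbatim.

H3K4me3 and H3K27ac consensus sets are then intersected to classify elements:
regions carrying both marks (>= min_overlap of the shorter) are merged into
dual-marked promoters; leftover H3K4me3-only regions are promoters without
acetylation; leftover H3K27ac-only regions are enhancers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, MarkClass

__all__ = [
    "ReplicatePeak",
    "ConsensusElement",
    "build_consensus",
    "classify_elements",
    "element_intensity",
]


@dataclass(frozen=True)
class ReplicatePeak:
    """A single MACS-style enriched region from one biological replicate."""

    interval: GenomicInterval
    mark: str  # "H3K4me3" or "H3K27ac"
    replicate: str
    fold_enrichment: float

    def __post_init__(self) -> None:
        if self.fold_enrichment <= 0:
            raise ValueError("fold_enrichment must be positive")


@dataclass
class ConsensusElement:
    """A reproducible merged region, optionally classified by mark content."""

    interval: GenomicInterval
    mark_class: MarkClass | None
    intensity: float
    reproducibility: float
    supporting_replicates: tuple[str, ...]
    mark_spans: dict = field(default_factory=dict)  # mark -> GenomicInterval

    @property
    def length(self) -> int:
        return self.interval.length


def element_intensity(peaks: Sequence[ReplicatePeak]) -> float:
    """Mean fold enrichment across supporting replicates.

    Each replicate contributes the mean of its own supporting peaks, and the
    replicate-level values are averaged, so one fragmented replicate does not
    dominate.
    """
    if not peaks:
        raise ValueError("element_intensity requires at least one supporting peak")
    by_rep: dict[str, list[float]] = {}
    for p in peaks:
        by_rep.setdefault(p.replicate, []).append(p.fold_enrichment)
    return float(np.mean([np.mean(v) for v in by_rep.values()]))


def _qualifying(a: ReplicatePeak, b: ReplicatePeak, min_overlap: float) -> bool:
    ia, ib = a.interval, b.interval
    if ia.chrom != ib.chrom:
        return False
    ov = min(ia.end, ib.end) - max(ia.start, ib.start)
    return ov >= min_overlap * min(ia.length, ib.length) and ov > 0


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def build_consensus(
    replicate_peaks: Sequence[ReplicatePeak],
    n_replicates: int | None = None,
    min_replicates: int = 2,
    min_overlap: float = 0.5,
    single_replicate_ok: bool = False,
) -> list[ConsensusElement]:
    """Build consensus regions for one species and one mark.

    Parameters
    ----------
    replicate_peaks : sequence of ReplicatePeak
        Peaks pooled across all replicates of one (species, mark).
    n_replicates : int, optional
        Total number of replicates profiled (defaults to the number of
        distinct replicate ids seen; pass explicitly when a replicate called
        zero peaks so reproducibility fractions stay honest).
    min_replicates : int
        Minimum number of distinct replicates a consensus region must draw
        support from (default 2).
    min_overlap : float
        Fraction (of the shorter peak) two peaks must share to count as the
        same region (default 0.5).
    single_replicate_ok : bool
        Retain all peaks verbatim when only one replicate exists (the
        single-individual species code path).
    """
    if not 0 < min_overlap <= 1:
        raise ValueError("min_overlap must be in (0, 1]")
    peaks = sorted(replicate_peaks,
                   key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    if not peaks:
        return []
    reps = sorted({p.replicate for p in peaks})
    total_reps = n_replicates if n_replicates is not None else len(reps)

    if total_reps == 1:
        if not single_replicate_ok and min_replicates > 1:
            import warnings

            warnings.warn(
                "min_replicates exceeds the number of replicates; "
                "no consensus regions (pass single_replicate_ok to retain peaks)"
            )
            return []
        return [
            ConsensusElement(
                interval=p.interval,
                mark_class=None,
                intensity=p.fold_enrichment,
                reproducibility=1.0,
                supporting_replicates=(p.replicate,),
                mark_spans={p.mark: p.interval},
            )
            for p in peaks
        ]

    n = len(peaks)
    partners: list[set[str]] = [set() for _ in range(n)]
    edges: list[tuple[int, int]] = []
    # sweep: peaks sorted by start; only nearby peaks can overlap
    for i in range(n):
        pi = peaks[i]
        for j in range(i + 1, n):
            pj = peaks[j]
            if pj.interval.chrom != pi.interval.chrom or pj.interval.start >= pi.interval.end:
                break
            if _qualifying(pi, pj, min_overlap):
                edges.append((i, j))
                if pi.replicate != pj.replicate:
                    partners[i].add(pj.replicate)
                    partners[j].add(pi.replicate)

    reproducible = {
        i for i in range(n) if len(partners[i]) >= min_replicates - 1
    }
    # merge groups: components of the overlap graph induced on reproducible
    # peaks (discarded peaks cannot bridge two consensus regions)
    dsu = _DSU(n)
    for i, j in edges:
        if i in reproducible and j in reproducible:
            dsu.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in sorted(reproducible):
        groups.setdefault(dsu.find(i), []).append(i)

    out = []
    for members in groups.values():
        mpeaks = [peaks[i] for i in members]
        start = min(p.interval.start for p in mpeaks)
        end = max(p.interval.end for p in mpeaks)
        sp = mpeaks[0].interval.species
        chrom = mpeaks[0].interval.chrom
        support = tuple(sorted({p.replicate for p in mpeaks}))
        mark = mpeaks[0].mark
        iv = GenomicInterval(sp, chrom, start, end)
        out.append(
            ConsensusElement(
                interval=iv,
                mark_class=None,
                intensity=element_intensity(mpeaks),
                reproducibility=len(support) / total_reps,
                supporting_replicates=support,
                mark_spans={mark: iv},
            )
        )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return out


def classify_elements(
    k4_consensus: Sequence[ConsensusElement],
    k27_consensus: Sequence[ConsensusElement],
    min_overlap: float = 0.5,
) -> list[ConsensusElement]:
    """Partition consensus regions into dual promoters, K4-only promoters and
    enhancers.

    K4/K27 consensus pairs sharing >= ``min_overlap`` of the shorter region are
    merged (transitively) into ``promoter_dual`` elements spanning both marks;
    unpaired H3K4me3 regions become ``promoter_k4`` and unpaired H3K27ac
    regions become ``enhancer``.  Every input region ends up in exactly one
    output element.
    """
    k4 = list(k4_consensus)
    k27 = list(k27_consensus)
    n4, n27 = len(k4), len(k27)
    allc = k4 + k27
    dsu = _DSU(n4 + n27)
    dual = [False] * (n4 + n27)

    order = sorted(range(n4 + n27),
                   key=lambda i: (allc[i].interval.chrom, allc[i].interval.start))
    for a_pos in range(len(order)):
        i = order[a_pos]
        ci = allc[i].interval
        for b_pos in range(a_pos + 1, len(order)):
            j = order[b_pos]
            cj = allc[j].interval
            if cj.chrom != ci.chrom or cj.start >= ci.end:
                break
            if (i < n4) == (j < n4):
                continue  # same mark
            ov = min(ci.end, cj.end) - max(ci.start, cj.start)
            if ov > 0 and ov >= min_overlap * min(ci.length, cj.length):
                dsu.union(i, j)
                dual[i] = dual[j] = True

    groups: dict[int, list[int]] = {}
    for i in range(n4 + n27):
        groups.setdefault(dsu.find(i), []).append(i)

    out = []
    for members in groups.values():
        cs = [allc[i] for i in members]
        has4 = any(i < n4 for i in members)
        has27 = any(i >= n4 for i in members)
        if has4 and has27:
            klass = MarkClass.promoter_dual
        elif has4:
            klass = MarkClass.promoter_k4
        else:
            klass = MarkClass.enhancer
        sp = cs[0].interval.species
        chrom = cs[0].interval.chrom
        start = min(c.interval.start for c in cs)
        end = max(c.interval.end for c in cs)
        spans: dict[str, GenomicInterval] = {}
        for idx, c in zip(members, cs):
            mark = "H3K4me3" if idx < n4 else "H3K27ac"
            prev = spans.get(mark)
            if prev is None:
                spans[mark] = c.interval
            else:
                spans[mark] = GenomicInterval(
                    sp, chrom, min(prev.start, c.interval.start),
                    max(prev.end, c.interval.end))
        out.append(
            ConsensusElement(
                interval=GenomicInterval(sp, chrom, start, end),
                mark_class=klass,
                intensity=float(np.mean([c.intensity for c in cs])),
                reproducibility=float(np.mean([c.reproducibility for c in cs])),
                supporting_replicates=tuple(
                    sorted({r for c in cs for r in c.supporting_replicates})
                ),
                mark_spans=spans,
            )
        )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return out


def consensus_to_frame(elements: Sequence[ConsensusElement]) -> pd.DataFrame:
    """Tabulate consensus elements (BED6+3 layout: class, intensity, reprod)."""
    rows = []
    for i, el in enumerate(elements):
        rows.append(
            {
                "species": el.interval.species,
                "chrom": el.interval.chrom,
                "start": el.interval.start,
                "end": el.interval.end,
                "name": f"cons_{i}",
                "score": 0,
                "strand": ".",
                "mark_class": el.mark_class.value if el.mark_class else ".",
                "intensity": el.intensity,
                "reproducibility": el.reproducibility,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["species", "chrom", "start", "end", "name", "score", "strand",
                 "mark_class", "intensity", "reproducibility"],
    )
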
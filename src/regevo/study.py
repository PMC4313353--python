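"""End-to-end study assembly on a synthetic (or loaded) world.

Thin orchestration over the analysis modules: build classified consensus
elements for every species, derive per-mark conservation call tables for an
anchor species, and assemble class-wise pairwise conservation matrices.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conserved_sets import MARKS, MarkCallTable
from .intervals import GenomicInterval, MarkClass
from .orthomap import ElementIndex, OrthologyMap
from .peaks import ConsensusElement, build_consensus, classify_elements
from .simulate import SyntheticWorld
from .turnover import pairwise_ratio_matrix

__all__ = [
    "species_consensus",
    "all_consensus",
    "mark_bearing_intervals",
    "class_intervals",
    "anchor_call_table",
    "class_ratio_matrix",
    "match_to_truth",
]


def species_consensus(
    world: SyntheticWorld, species: str,
    min_replicates: int = 2, min_overlap: float = 0.5,
) -> list[ConsensusElement]:
    """Replicate peaks -> classified consensus elements for one species."""
    nreps = world.n_replicates(species)
    per_mark = {}
    for mark in MARKS:
        per_mark[mark] = build_consensus(
            world.replicate_peak_objects(species, mark),
            n_replicates=nreps,
            min_replicates=min_replicates,
            min_overlap=min_overlap,
            single_replicate_ok=(nreps == 1),
        )
    return classify_elements(per_mark["H3K4me3"], per_mark["H3K27ac"],
                             min_overlap=min_overlap)


def all_consensus(world: SyntheticWorld, **kwargs) -> dict[str, list[ConsensusElement]]:
    return {s: species_consensus(world, s, **kwargs) for s in world.species}


def mark_bearing_intervals(
    consensus: Sequence[ConsensusElement], mark: str
) -> list[GenomicInterval]:
    """Intervals of consensus elements carrying a given histone mark."""
    return [c.interval for c in consensus if mark in c.mark_class.marks]


def class_intervals(
    consensus: Sequence[ConsensusElement], mark_class: MarkClass
) -> list[GenomicInterval]:
    return [c.interval for c in consensus if c.mark_class is mark_class]


def anchor_call_table(
    world: SyntheticWorld,
    anchor: str,
    consensus: Mapping[str, Sequence[ConsensusElement]],
    min_overlap: float = 0.5,
) -> tuple[MarkCallTable, dict[str, ConsensusElement]]:
    """Per-mark conservation calls of anchor consensus elements vs all
    other species.

    Returns the call table plus a mapping from anchor element id to the
    anchor :class:`ConsensusElement` (ids are ``{anchor}_c{i}``).
    """
    anchor_els = {f"{anchor}_c{i}": el for i, el in enumerate(consensus[anchor])}
    ids = list(anchor_els)
    others = [s for s in world.species if s != anchor]
    by_chrom: dict[str, list[str]] = {}
    for eid in ids:
        by_chrom.setdefault(anchor_els[eid].interval.chrom, []).append(eid)

    conserved = {m: pd.DataFrame(False, index=ids, columns=others) for m in MARKS}
    alignable = pd.DataFrame(False, index=ids, columns=others)
    for s in others:
        omap = world.orthology_map(anchor, s)
        tchrom = omap.blocks.chrom_b.iloc[0]
        indices = {m: ElementIndex(mark_bearing_intervals(consensus[s], m))
                   for m in MARKS}
        for chrom, eids in by_chrom.items():
            starts = np.array([anchor_els[e].interval.start for e in eids], np.int64)
            ends = np.array([anchor_els[e].interval.end for e in eids], np.int64)
            status, ts, te = omap.project_many(starts, ends, chrom)
            uniq = status == 0
            alignable.loc[eids, s] = uniq
            if uniq.any():
                plen = te[uniq] - ts[uniq]
                sel = [e for e, u in zip(eids, uniq) if u]
                for m in MARKS:
                    ov = indices[m].best_overlap_many(tchrom, ts[uniq], te[uniq])
                    conserved[m].loc[sel, s] = ov >= min_overlap * plen
    return MarkCallTable(conserved, alignable), anchor_els


def class_ratio_matrix(
    world: SyntheticWorld,
    consensus: Mapping[str, Sequence[ConsensusElement]],
    mark_class: MarkClass,
    min_overlap: float = 0.5,
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Reciprocal-averaged pairwise conservation ratio matrix for one class.

    Conservation in the partner species is called against all regions
    bearing the class's defining mark (H3K4me3 for promoters, H3K27ac for
    enhancers), so a class flip that keeps the mark does not count as loss.
    """
    sp = list(species) if species is not None else world.species
    defining = "H3K4me3" if mark_class.is_promoter else "H3K27ac"
    anchors = {s: class_intervals(consensus[s], mark_class) for s in sp}
    targets = {s: mark_bearing_intervals(consensus[s], defining) for s in sp}
    mat = pd.DataFrame(np.nan, index=sp, columns=sp, dtype=float)
    np.fill_diagonal(mat.values, 1.0)
    for i, a in enumerate(sp):
        for b in sp[i + 1:]:
            omap = world.orthology_map(a, b)
            val = np.nanmean([
                _directional_only(anchors[a], targets[b], omap, min_overlap),
                _directional_only(anchors[b], targets[a], omap.reversed(), min_overlap),
            ])
            mat.loc[a, b] = mat.loc[b, a] = val
    return mat


def _directional_only(anchors, targets, omap, min_overlap):
    from .orthomap import ElementIndex, _directional_counts

    if not anchors:
        return np.nan
    c, n = _directional_counts(anchors, omap, ElementIndex(targets), min_overlap)
    return c / n if n else np.nan


def match_to_truth(
    world: SyntheticWorld, species: str,
    consensus: Sequence[ConsensusElement],
    min_overlap: float = 0.5,
) -> dict[int, str | None]:
    """Map consensus element index -> true element id (or None for noise).

    A consensus element matches the true element present in the species that
    overlaps it by >= ``min_overlap`` of the shorter of the two.
    """
    truth = world.element_intervals(species, present_only=True)
    index_items = list(truth.items())
    starts = np.array([iv.start for _, iv in index_items], np.int64)
    order = np.argsort(starts)
    starts = starts[order]
    ends = np.array([iv.end for _, iv in index_items], np.int64)[order]
    tids = np.array([eid for eid, _ in index_items], object)[order]
    out: dict[int, str | None] = {}
    for i, el in enumerate(consensus):
        s, e = el.interval.start, el.interval.end
        lo = int(np.searchsorted(ends, s, side="right"))
        hi = int(np.searchsorted(starts, e, side="left"))
        best, best_id = 0, None
        for k in range(lo, hi):
            ov = min(e, ends[k]) - max(s, starts[k])
            if ov > best:
                best, best_id = ov, tids[k]
        if best_id is not None:
            # require >= min_overlap of the shorter of consensus and match
            k = int(np.where(tids == best_id)[0][0])
            tlen = ends[k] - starts[k]
            if best < min_overlap * min(e - s, tlen):
                best_id = None
        out[i] = best_id
    return out
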
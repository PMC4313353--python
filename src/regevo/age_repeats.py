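"""Sequence-age assignment and repeat-family enrichment.

The sequence age of a recently evolved element is the divergence time of the
most distant species with an alignable (uniquely projecting) ortholog of its
DNA — the element's regulatory activity is new, but the sequence it sits in
may be ancient (exaptation).  Ages are binned as young (0–40 Ma), mid
(40–100 Ma) and ancestral (>= 100 Ma); element DNA alignable nowhere has age
0 (strictly species-specific sequence).

Repeat enrichment compares the fraction of foreground elements containing a
repeat of each family against a background element set with a one-sided
binomial test and Benjamini–Hochberg correction across families.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval
from .phylo import SpeciesTree

__all__ = [
    "AGE_BINS",
    "age_category",
    "sequence_age",
    "repeat_overlap_counts",
    "repeat_enrichment",
    "EnrichmentResult",
]

AGE_BINS = ((0.0, 40.0, "young"), (40.0, 100.0, "mid"), (100.0, math.inf, "ancestral"))


def age_category(age_ma: float) -> str:
    """Bin a sequence age (Ma) into young / mid / ancestral."""
    if age_ma < 0:
        raise ValueError("age must be >= 0")
    for lo, hi, name in AGE_BINS:
        if lo <= age_ma < hi:
            return name
    return "ancestral"


def sequence_age(
    reference: str,
    projection_status: Mapping[str, str],
    tree: SpeciesTree,
) -> tuple[float, str]:
    """Age (Ma) and category of an element's DNA seen from the reference.

    ``projection_status`` maps each compared species to its projection
    outcome ("unique" / "split" / "unmapped"); only unique projections count
    as alignable.
    """
    age = 0.0
    for s, status in projection_status.items():
        if s != reference and status == "unique":
            age = max(age, tree.divergence_time(reference, s))
    return age, age_category(age)


def repeat_overlap_counts(
    elements: Mapping[str, GenomicInterval],
    repeats: pd.DataFrame,
    min_overlap: float = 0.5,
    by: str = "repeat_family",
) -> dict[str, int]:
    """Number of elements containing >= 1 repeat of each family (or class).

    A repeat is *contained* in an element when the overlap covers at least
    ``min_overlap`` of the repeat's length (repeats are typically much
    shorter than elements).  An element counts at most once per family even
    when it holds several copies.
    """
    trees: dict[str, IntervalTree] = {}
    for eid, iv in elements.items():
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, eid)
    hits: dict[str, set[str]] = {}
    for r in repeats.itertuples(index=False):
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        rlen = r.end - r.start
        for ov in tree.overlap(r.start, r.end):
            shared = min(ov.end, r.end) - max(ov.begin, r.start)
            if shared >= min_overlap * rlen:
                hits.setdefault(getattr(r, by), set()).add(ov.data)
    return {fam: len(ids) for fam, ids in hits.items()}


@dataclass
class EnrichmentResult:
    unit: str
    fg_count: int
    fg_total: int
    bg_count: int
    bg_total: int
    fold: float
    p: float
    q: float
    bg_rate_floored: bool = False


def repeat_enrichment(
    fg_counts: Mapping[str, int],
    fg_total: int,
    bg_counts: Mapping[str, int],
    bg_total: int,
    units: Sequence[str] | None = None,
) -> list[EnrichmentResult]:
    """One-sided binomial enrichment per repeat family with BH correction.

    For each family, tests whether the foreground fraction of elements
    containing the family exceeds the background fraction:
    ``p = P(Bin(fg_total, bg_count / bg_total) >= fg_count)``.  Families with
    ``bg_count = 0`` get a floored background rate of ``0.5 / bg_total`` so
    the test is defined (flagged in the result).
    """
    if fg_total <= 0 or bg_total <= 0:
        raise ValueError("totals must be positive")
    if fg_total > bg_total:
        raise ValueError("foreground cannot exceed background size")
    if units is None:
        units = sorted(set(fg_counts) | set(bg_counts))
    results = []
    pvals = []
    for unit in units:
        k = int(fg_counts.get(unit, 0))
        bk = int(bg_counts.get(unit, 0))
        if k > fg_total or bk > bg_total:
            raise ValueError(f"count exceeds total for {unit}")
        floored = bk == 0
        if floored:
            warnings.warn(f"background count 0 for {unit}; applying rate floor")
        rate = max(bk, 0.5) / bg_total if floored else bk / bg_total
        p = float(st.binom.sf(k - 1, fg_total, rate))  # upper tail, >= k
        fg_frac = k / fg_total
        bg_frac = bk / bg_total
        fold = math.inf if bg_frac == 0 and fg_frac > 0 else (
            fg_frac / bg_frac if bg_frac > 0 else float("nan"))
        results.append((unit, k, bk, fold, p, floored))
        pvals.append(p)
    if not results:
        return []
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        EnrichmentResult(unit, k, fg_total, bk, bg_total, fold, p, float(q),
                         floored)
        for (unit, k, bk, fold, p, floored), q in zip(results, qvals)
    ]
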
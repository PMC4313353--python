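"""Regulatory-element turnover: conservation profiles, exponential decay
fits, and distance-based phylogeny reconstruction.

The central quantity is the pairwise conservation ratio r(t) between species
separated by divergence time t.  Under memoryless (exponential) element loss
the expected ratio decays as ``r(t) = A * exp(-t / tau)``; the fit is an
ordinary least-squares regression of ``ln r`` on ``t`` (the decay is a
straight line on a log scale), with the half-life ``tau * ln 2`` and its 95%
confidence interval obtained from the t-interval on the slope.  The free
amplitude A absorbs technical non-conservation at t -> 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .intervals import GenomicInterval
from .orthomap import ElementIndex, OrthologyMap, pairwise_conservation_ratio
from .phylo import SpeciesTree

__all__ = [
    "ConservationProfile",
    "DecayFit",
    "conservation_profile",
    "conservation_ratio",
    "fit_exponential_decay",
    "fit_decay_jackknife",
    "mean_lifetime",
    "pairwise_ratio_matrix",
    "decay_points_from_matrix",
    "nj_tree",
]

LN2 = math.log(2.0)


@dataclass
class ConservationProfile:
    """Per anchor element: where its DNA aligns and where activity persists."""

    element_id: str
    n_alignable: int
    n_conserved: int
    calls: dict[str, str] = field(default_factory=dict)  # species -> call


def conservation_profile(
    anchor_elements: Mapping[str, GenomicInterval],
    maps: Mapping[str, OrthologyMap],
    target_indices: Mapping[str, ElementIndex],
    min_overlap: float = 0.5,
) -> list[ConservationProfile]:
    """Profile each anchor element against every other species.

    Parameters
    ----------
    anchor_elements : mapping of element id -> interval (anchor species)
    maps : mapping of target species -> OrthologyMap (anchor on side A)
    target_indices : mapping of target species -> ElementIndex of marked
        regions to test conservation against.
    """
    ids = list(anchor_elements)
    by_chrom: dict[str, list[str]] = {}
    for eid in ids:
        by_chrom.setdefault(anchor_elements[eid].chrom, []).append(eid)

    calls: dict[str, dict[str, str]] = {eid: {} for eid in ids}
    for species, omap in maps.items():
        index = target_indices[species]
        tchrom = omap.blocks.chrom_b.iloc[0]
        for chrom, eids in by_chrom.items():
            starts = np.array([anchor_elements[e].start for e in eids], np.int64)
            ends = np.array([anchor_elements[e].end for e in eids], np.int64)
            status, ts, te = omap.project_many(starts, ends, chrom)
            ov = np.zeros(len(eids), np.int64)
            uniq = status == 0
            if uniq.any():
                ov[uniq] = index.best_overlap_many(tchrom, ts[uniq], te[uniq])
            for i, eid in enumerate(eids):
                if status[i] != 0:
                    calls[eid][species] = "unalignable"
                elif ov[i] >= min_overlap * (te[i] - ts[i]):
                    calls[eid][species] = "conserved"
                else:
                    calls[eid][species] = "absent"

    out = []
    for eid in ids:
        c = calls[eid]
        n_align = sum(1 for v in c.values() if v != "unalignable")
        n_cons = sum(1 for v in c.values() if v == "conserved")
        out.append(ConservationProfile(eid, n_align, n_cons, c))
    return out


def conservation_ratio(profile: ConservationProfile) -> float:
    """Conserved fraction among mapped species; NaN when nothing aligns."""
    if profile.n_alignable == 0:
        return float("nan")
    return profile.n_conserved / profile.n_alignable


@dataclass
class DecayFit:
    """Result of a log-linear exponential decay fit."""

    tau: float            # mean lifetime, Ma
    half_life: float      # tau * ln2, Ma
    amplitude: float      # fitted ratio at t = 0
    ci95_half_life: tuple[float, float]
    r_squared: float
    n_points: int

    def ci_covers(self, value: float) -> bool:
        lo, hi = self.ci95_half_life
        return lo <= value <= hi


def fit_exponential_decay(
    times: Sequence[float],
    ratios: Sequence[float],
    fix_amplitude: bool = False,
) -> DecayFit:
    """Fit ``ratio = A * exp(-t / tau)`` by OLS on the log scale.

    Non-positive ratios cannot be log-transformed and are dropped with a
    warning.  ``fix_amplitude`` constrains A = 1 (regression through the
    origin on the log scale).  The 95% CI on the half-life is the monotone
    transform of the t-interval on the slope; when the slope interval crosses
    zero the upper bound is infinite.
    """
    t = np.asarray(times, float)
    r = np.asarray(ratios, float)
    keep = r > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} non-positive ratio points")
        t, r = t[keep], r[keep]
    if len(t) < 3:
        raise ValueError("need at least 3 points with positive ratios")
    if np.ptp(t) == 0:
        raise ValueError("all points at the same divergence time")
    y = np.log(r)

    if fix_amplitude:
        slope = float(np.sum(t * y) / np.sum(t * t))
        resid = y - slope * t
        dof = len(t) - 1
        se = math.sqrt(float(np.sum(resid**2)) / dof / float(np.sum(t * t)))
        intercept = 0.0
        ss_tot = float(np.sum(y**2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    else:
        res = st.linregress(t, y)
        slope, intercept, se = float(res.slope), float(res.intercept), float(res.stderr)
        dof = len(t) - 2
        r2 = float(res.rvalue**2)

    if slope >= 0:
        raise ValueError("no decay detected (non-negative slope)")
    tau = -1.0 / slope
    half_life = tau * LN2
    tcrit = st.t.ppf(0.975, dof)
    slope_lo, slope_hi = slope - tcrit * se, slope + tcrit * se
    # half-life is -ln2/slope, monotone increasing in slope on (-inf, 0)
    hl_lo = -LN2 / slope_lo
    hl_hi = -LN2 / slope_hi if slope_hi < 0 else math.inf
    return DecayFit(
        tau=tau,
        half_life=half_life,
        amplitude=float(math.exp(intercept)),
        ci95_half_life=(hl_lo, hl_hi),
        r_squared=r2,
        n_points=len(t),
    )


def fit_decay_jackknife(
    ratio_matrix: pd.DataFrame,
    tree: SpeciesTree,
    time_scale: str = "divergence",
) -> DecayFit:
    """Decay fit with a delete-one-species jackknife confidence interval.

    Pairwise ratio points are not independent — every species contributes to
    many pairs, so the plain OLS residual CI is too narrow.  The slope is
    estimated from all pairs; its standard error comes from refitting with
    each species removed in turn (the standard remedy for pairwise
    comparative data), with a t-interval on n_species - 1 df.
    """
    species = list(ratio_matrix.index)
    if len(species) < 4:
        raise ValueError("jackknife CI needs at least 4 species")

    def _slope(subset: list[str]) -> float:
        sub = ratio_matrix.loc[subset, subset]
        t, r = decay_points_from_matrix(sub, tree, time_scale)
        keep = r > 0
        return float(st.linregress(t[keep], np.log(r[keep])).slope)

    t_all, r_all = decay_points_from_matrix(ratio_matrix, tree, time_scale)
    base = fit_exponential_decay(t_all, r_all)
    g = len(species)
    thetas = np.array([_slope([s for s in species if s != x]) for x in species])
    se = math.sqrt((g - 1) / g * float(np.sum((thetas - thetas.mean()) ** 2)))
    slope = -1.0 / base.tau
    tcrit = st.t.ppf(0.975, g - 1)
    lo, hi = slope - tcrit * se, slope + tcrit * se
    hl_lo = -LN2 / lo
    hl_hi = -LN2 / hi if hi < 0 else math.inf
    return DecayFit(base.tau, base.half_life, base.amplitude,
                    (hl_lo, hl_hi), base.r_squared, base.n_points)


def mean_lifetime(half_life: float) -> float:
    """Mean lifetime tau = half_life / ln 2 of an exponentially decaying pool."""
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    return half_life / LN2


def pairwise_ratio_matrix(
    elements: Mapping[str, Sequence[GenomicInterval]],
    maps: Mapping[tuple[str, str], OrthologyMap],
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Symmetric matrix of reciprocal-averaged conservation ratios.

    ``maps[(a, b)]`` projects species ``a`` coordinates onto ``b``; only one
    orientation per unordered pair is required (the reverse is derived).
    Diagonal is 1 (self-comparison).
    """
    species = list(elements)
    mat = pd.DataFrame(np.nan, index=species, columns=species, dtype=float)
    np.fill_diagonal(mat.values, 1.0)
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            if (a, b) in maps:
                m_ab, m_ba = maps[(a, b)], maps.get((b, a))
            elif (b, a) in maps:
                m_ab, m_ba = maps[(b, a)].reversed(), maps[(b, a)]
            else:
                continue
            ratio = pairwise_conservation_ratio(
                elements[a], elements[b], m_ab, m_ba, min_overlap=min_overlap
            )
            mat.loc[a, b] = mat.loc[b, a] = ratio
    return mat


def decay_points_from_matrix(
    ratio_matrix: pd.DataFrame,
    tree: SpeciesTree,
    time_scale: str = "divergence",
) -> tuple[np.ndarray, np.ndarray]:
    """Unordered species pairs -> (time, ratio) points for the decay fit.

    ``time_scale`` is ``"divergence"`` (MRCA age, the conventional x-axis for
    reporting half-lives) or ``"total_branch"`` (sum of both lineages' path
    lengths, i.e. twice the divergence on an ultrametric tree — the clock
    under which per-lineage loss rates are directly identified).
    """
    if time_scale not in ("divergence", "total_branch"):
        raise ValueError("time_scale must be 'divergence' or 'total_branch'")
    species = list(ratio_matrix.index)
    times, ratios = [], []
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            r = ratio_matrix.loc[a, b]
            if np.isnan(r):
                continue
            t = tree.divergence_time(a, b)
            if time_scale == "total_branch":
                t *= 2.0
            times.append(t)
            ratios.append(float(r))
    return np.array(times), np.array(ratios)


def nj_tree(distance_matrix: pd.DataFrame) -> str:
    """Neighbor-joining (Saitou–Nei) tree from a pairwise distance matrix.

    Distances are typically ``1 - pairwise_conservation_ratio``.  Negative
    branch lengths are clamped to zero.  Returns a newick string.
    """
    if distance_matrix.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    vals = distance_matrix.to_numpy(float)
    if not np.allclose(vals, vals.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(vals) != 0):
        raise ValueError("distance matrix must have zero diagonal")
    dm = DistanceMatrix(vals, list(distance_matrix.index))
    tree = _skbio_nj(dm, neg_as_zero=True)
    return str(tree).strip()
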
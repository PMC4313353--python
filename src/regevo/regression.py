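"""Explaining conservation ratios from element features.

Per-element conservation ratios (conserved species / mapped species) are
modelled by ordinary least squares on experimental and sequence features
(reproducibility, intensity, length, TSS distance, GC content, constraint
fraction, TF binding-site count).  The variance decomposition reports each
feature's univariate R², the cumulative R² as features are added
left-to-right to a multiple regression, and the pairwise R² between
features (squared Pearson correlations) that explains why correlated
features add little once their partners are in the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "DEFAULT_FEATURE_ORDER",
    "constraint_fraction",
    "incremental_r2",
    "VarianceDecomposition",
]

DEFAULT_FEATURE_ORDER = (
    "reproducibility", "intensity", "length", "tss_distance",
    "gc_content", "constraint_fraction", "tfbs_count",
)


def constraint_fraction(
    element: GenomicInterval, constrained: pd.DataFrame
) -> float:
    """Fraction of element bases covered by constrained segments.

    ``constrained`` is a BED-style frame (chrom/start/end); overlapping
    segments are collapsed before counting so no base is counted twice.
    """
    sub = constrained[constrained["chrom"] == element.chrom]
    if sub.empty:
        return 0.0
    spans = sorted(zip(sub["start"], sub["end"]))
    covered = 0
    cur_end = -1
    for s, e in spans:
        s = max(s, element.start, cur_end)
        e = min(e, element.end)
        if e > s:
            covered += e - s
            cur_end = e
    return covered / element.length


@dataclass
class VarianceDecomposition:
    feature_order: tuple[str, ...]
    marginal_r2: pd.Series       # univariate R² per feature
    cumulative_r2: pd.Series     # R² of prefix models
    full_r2: float
    pairwise_r2: pd.DataFrame    # squared Pearson correlation between features
    dropped: tuple[str, ...] = ()


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    A = np.column_stack([np.ones(len(y)), X])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def incremental_r2(
    table: pd.DataFrame,
    feature_order: Sequence[str] = DEFAULT_FEATURE_ORDER,
    response: str = "conservation_ratio",
) -> VarianceDecomposition:
    """Marginal, cumulative and pairwise R² for an ordered feature list.

    Rows with any non-finite value are dropped; constant or collinear
    features are dropped from the cumulative sequence with a warning (their
    marginal R² is still reported, as 0 for constants).
    """
    feats = [f for f in feature_order if f in table.columns]
    missing = set(feature_order) - set(feats)
    if missing:
        raise KeyError(f"features not in table: {sorted(missing)}")
    df = table[feats + [response]].apply(pd.to_numeric)
    df = df[np.isfinite(df).all(axis=1)]
    if len(df) < len(feats) + 2:
        raise ValueError("not enough complete rows for the requested features")
    y = df[response].to_numpy(float)
    X = df[feats].to_numpy(float)

    marginal = {}
    for j, f in enumerate(feats):
        marginal[f] = 0.0 if np.ptp(X[:, j]) == 0 else _ols_r2(X[:, [j]], y)

    dropped: list[str] = []
    kept_idx: list[int] = []
    cumulative = {}
    for j, f in enumerate(feats):
        trial = kept_idx + [j]
        A = np.column_stack([np.ones(len(y)), X[:, trial]])
        if np.linalg.matrix_rank(A) < A.shape[1]:
            warnings.warn(f"dropping collinear/constant feature {f!r}")
            dropped.append(f)
            cumulative[f] = cumulative[feats[j - 1]] if j else 0.0
            continue
        kept_idx = trial
        cumulative[f] = _ols_r2(X[:, kept_idx], y)

    corr = np.corrcoef(X, rowvar=False)
    pairwise = pd.DataFrame(corr**2, index=feats, columns=feats)
    return VarianceDecomposition(
        feature_order=tuple(feats),
        marginal_r2=pd.Series(marginal)[feats],
        cumulative_r2=pd.Series(cumulative)[feats],
        full_r2=_ols_r2(X[:, kept_idx], y) if kept_idx else 0.0,
        pairwise_r2=pairwise,
        dropped=tuple(dropped),
    )
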
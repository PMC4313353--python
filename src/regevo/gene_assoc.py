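"""Gene–element association and gene-set statistics.

Regulatory domains follow the basal-plus-extension rule: each gene gets a
basal domain of 5 kb upstream / 1 kb downstream of its TSS (strand
oriented); the domain then extends in both directions to the nearest
neighbouring gene's basal domain, but no more than 1 Mb beyond the basal
edge on either side, clipped to the chromosome.  An element is associated
with every gene whose regulatory domain it overlaps by at least one base.

Tissue specificity: ``tsps(g) = x_target / mean(x_other)`` with missing
expression imputed as 0.  Liver-specific genes satisfy tsps > 1.5, liver is
the argmax tissue, and liver RPKM > 10.
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

__all__ = [
    "GeneModel",
    "build_regulatory_domains",
    "associate_elements",
    "tsps_and_liver_specific",
    "geneset_enrichment_binomial",
    "psg_enrichment",
    "expression_ratio_profile",
    "GeneSetTestResult",
]

BASAL_UP = 5000
BASAL_DOWN = 1000
MAX_EXTENSION = 1_000_000


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    basal_start: int
    basal_end: int
    domain_start: int
    domain_end: int

    @property
    def domain_length(self) -> int:
        return self.domain_end - self.domain_start


def build_regulatory_domains(
    genes: pd.DataFrame, chrom_lengths: Mapping[str, int]
) -> list[GeneModel]:
    """Basal-plus-extension regulatory domains for a gene table.

    ``genes`` needs columns gene_id, chrom, tss, strand (one consensus TSS
    per gene).  Extension stops at the nearest neighbouring basal edge, is
    capped at 1 Mb beyond the basal edge per side, and is clipped to
    ``chrom_lengths``.
    """
    models: list[GeneModel] = []
    for chrom, sub in genes.groupby("chrom", sort=True):
        length = chrom_lengths[chrom]
        sub = sub.sort_values("tss", kind="mergesort")
        basal = []
        for r in sub.itertuples(index=False):
            if r.strand == "-":
                b0, b1 = r.tss - BASAL_DOWN, r.tss + BASAL_UP
            else:
                b0, b1 = r.tss - BASAL_UP, r.tss + BASAL_DOWN
            if b0 < 0 or b1 > length:
                warnings.warn(f"basal domain of {r.gene_id} clipped to chromosome")
            basal.append((max(0, b0), min(length, b1), r))
        for i, (b0, b1, r) in enumerate(basal):
            left_limit = max(0, b0 - MAX_EXTENSION)
            right_limit = min(length, b1 + MAX_EXTENSION)
            # nearest neighbouring basal edges (basal domains may interleave;
            # scan all, not just adjacent rows)
            left_candidates = [e1 for (s1, e1, _) in basal[:i] if e1 <= b0]
            right_candidates = [s1 for (s1, e1, _) in basal[i + 1:] if s1 >= b1]
            d0 = max([left_limit] + left_candidates)
            d1 = min([right_limit] + right_candidates)
            models.append(GeneModel(r.gene_id, chrom, int(r.tss), r.strand,
                                    b0, b1, int(d0), int(d1)))
    return models


def associate_elements(
    elements: Mapping[str, GenomicInterval],
    gene_models: Sequence[GeneModel],
) -> pd.DataFrame:
    """Element–gene links (>= 1 bp overlap with the regulatory domain).

    Returns a frame with one row per link: element_id, gene_id, and the
    signed distance from the element midpoint to the gene's TSS (negative =
    upstream of the TSS in gene orientation).
    """
    trees: dict[str, IntervalTree] = {}
    for gm in gene_models:
        trees.setdefault(gm.chrom, IntervalTree()).addi(
            gm.domain_start, gm.domain_end, gm)
    rows = []
    for eid, iv in elements.items():
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        mid = (iv.start + iv.end) // 2
        for hit in sorted(tree.overlap(iv.start, iv.end),
                          key=lambda h: h.data.gene_id):
            gm = hit.data
            d = mid - gm.tss
            if gm.strand == "-":
                d = -d
            rows.append((eid, gm.gene_id, int(d)))
    return pd.DataFrame(rows, columns=["element_id", "gene_id", "tss_distance"])


def tsps_and_liver_specific(
    expr: pd.DataFrame, target_tissue: str = "liver",
    tsps_threshold: float = 1.5, min_rpkm: float = 10.0,
) -> pd.DataFrame:
    """Tissue-specificity scores and the target-tissue-specific gene set.

    Returns a frame indexed by gene with columns ``tsps`` and ``selected``.
    Selection requires (1) tsps above the threshold, (2) the target tissue is
    the expression argmax, (3) target RPKM above ``min_rpkm``.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two tissues")
    if target_tissue not in expr.columns:
        raise KeyError(f"tissue {target_tissue!r} not in expression matrix")
    mat = expr.fillna(0.0)
    x_t = mat[target_tissue]
    others = mat.drop(columns=[target_tissue]).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsps = np.where(others > 0, x_t / others,
                        np.where(x_t > 0, np.inf, 0.0))
    argmax_is_target = mat.idxmax(axis=1) == target_tissue
    selected = (tsps > tsps_threshold) & argmax_is_target & (x_t > min_rpkm)
    return pd.DataFrame({"tsps": tsps, "selected": selected}, index=mat.index)


@dataclass
class GeneSetTestResult:
    name: str
    statistic: float
    p: float
    direction: str
    counts: tuple | None = None  # (k, n, K, N) for hypergeometric tests


def geneset_enrichment_binomial(
    fg_genes: Sequence[str],
    bg_genes: Sequence[str],
    annotation_sets: Mapping[str, Sequence[str]],
    q_threshold: float = 0.05,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Binomial term enrichment of foreground genes against a background.

    Per term: upper-tail binomial test of the foreground hit fraction at the
    background rate; BH across terms.  The ``reported`` column marks terms
    passing q < ``q_threshold`` with fold > ``fold_threshold``.
    """
    fg = set(fg_genes)
    bg = set(bg_genes)
    if not bg:
        raise ValueError("background gene set is empty")
    rows, pvals = [], []
    for term in sorted(annotation_sets):
        members = set(annotation_sets[term])
        k = len(fg & members)
        bg_k = len(bg & members)
        rate = bg_k / len(bg)
        if rate == 0:
            p = 1.0 if k == 0 else 0.0
        else:
            p = float(st.binom.sf(k - 1, len(fg), rate))
        fg_frac = k / len(fg) if fg else 0.0
        fold = fg_frac / rate if rate > 0 else (math.inf if k else float("nan"))
        rows.append((term, k, len(fg), bg_k, len(bg), fold, p))
        pvals.append(p)
    df = pd.DataFrame(rows, columns=["term", "fg_count", "fg_total",
                                     "bg_count", "bg_total", "fold", "p"])
    if len(df):
        df["q"] = multipletests(pvals, method="fdr_bh")[1]
        df["reported"] = (df["q"] < q_threshold) & (df["fold"] > fold_threshold)
    return df


def psg_enrichment(
    links_all_enhancers: pd.DataFrame,
    links_recent_enhancers: pd.DataFrame,
    gene_universe: Sequence[str],
    psg_list: Sequence[str],
) -> list[GeneSetTestResult]:
    """Association between recently evolved enhancers and positively
    selected genes (PSGs): three complementary tests, p-values uncorrected.

    (i)  hypergeometric on enhancer–gene links: are recent-enhancer links
         over-represented among links to PSG domains;
    (ii) hypergeometric on genes: do PSGs harbour >= 1 recent enhancer more
         often than other genes;
    (iii) one-sided Wilcoxon rank-sum on the per-gene proportion of recent
         enhancers among its enhancers (genes with >= 1 enhancer only).
    """
    psg = set(psg_list)
    if not psg:
        raise ValueError("PSG list is empty")
    universe = list(dict.fromkeys(gene_universe))
    unknown = psg - set(universe)
    if unknown:
        raise ValueError(f"PSGs outside the gene universe: {sorted(unknown)[:5]}")

    results = []
    # (i) link-level hypergeometric
    N = len(links_all_enhancers)
    K = int(links_all_enhancers["gene_id"].isin(psg).sum())
    n = len(links_recent_enhancers)
    k = int(links_recent_enhancers["gene_id"].isin(psg).sum())
    p1 = float(st.hypergeom.sf(k - 1, N, K, n)) if N else 1.0
    results.append(GeneSetTestResult(
        "recent_links_in_psg_domains", float(k), p1, "greater", (k, n, K, N)))

    # (ii) gene-level hypergeometric
    genes_with_recent = set(links_recent_enhancers["gene_id"])
    N2 = len(universe)
    K2 = len(psg)
    n2 = len(genes_with_recent & set(universe))
    k2 = len(genes_with_recent & psg)
    p2 = float(st.hypergeom.sf(k2 - 1, N2, K2, n2))
    results.append(GeneSetTestResult(
        "psgs_with_recent_enhancer", float(k2), p2, "greater", (k2, n2, K2, N2)))

    # (iii) Wilcoxon rank-sum on per-gene recent proportion
    total = links_all_enhancers.groupby("gene_id").size()
    recent = links_recent_enhancers.groupby("gene_id").size()
    prop = (recent.reindex(total.index).fillna(0.0) / total)
    is_psg = prop.index.isin(psg)
    x, y = prop[is_psg], prop[~is_psg]
    if len(x) == 0 or len(y) == 0:
        p3, stat = 1.0, float("nan")
    else:
        res = st.mannwhitneyu(x, y, alternative="greater")
        p3, stat = float(res.pvalue), float(res.statistic)
    results.append(GeneSetTestResult(
        "psg_recent_proportion_wilcoxon", stat, p3, "greater"))
    return results


def expression_ratio_profile(
    set_genes: Sequence[str],
    background_genes: Sequence[str],
    expr: pd.DataFrame,
) -> pd.Series:
    """Per-tissue mean expression of a gene set over a background set.

    Genes missing from the matrix count as unexpressed (RPKM 0); tissues with
    zero background mean yield NaN.
    """
    if len(set_genes) == 0 or len(background_genes) == 0:
        raise ValueError("gene sets must be non-empty")

    def _means(gene_ids):
        sub = expr.reindex(list(dict.fromkeys(gene_ids))).fillna(0.0)
        return sub.mean(axis=0)

    set_mean = _means(set_genes)
    bg_mean = _means(background_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = set_mean / bg_mean
    ratio[bg_mean == 0] = np.nan
    return ratio
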
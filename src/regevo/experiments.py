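"""Calibration, recovery and oracle-equivalence experiments.

Self-contained study-level experiments exercising the pipeline on synthetic
worlds with known ground truth: closed-form lifetime arithmetic, half-life
parameter recovery, phylogeny recovery from conservation distances,
permutation-test and FDR calibration, brute-force oracle equivalence on
randomized small instances, end-to-end truth recovery, and the power /
calibration of the PSG association tests.  Shared between the test suite
and the acceptance script.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.stats as st

from . import study
from .age_repeats import age_category, repeat_enrichment
from .conserved_sets import (MARKS, MarkCallTable, SpeciesPanel,
                             find_lineage_specific, find_recently_evolved,
                             permutation_test_conserved_count)
from .gene_assoc import build_regulatory_domains, psg_enrichment
from .intervals import GenomicInterval, MarkClass
from .orthomap import ElementIndex, OrthologyMap
from .peaks import ReplicatePeak, build_consensus
from .phylo import SpeciesTree
from .simulate import SimConfig, simulate_psg_links, simulate_world
from .turnover import (decay_points_from_matrix, fit_decay_jackknife,
                       fit_exponential_decay, mean_lifetime, nj_tree)

LN2 = math.log(2.0)

# 10-taxon high-quality panel tree (the default fixture pruned to the
# species with reference-grade genomes), root at 96 Ma.
PANEL_TREE_NEWICK = (
    "((((human:29,(macaque:13,vervet:13):16):14,marmoset:43):47,"
    "((mouse:20,rat:20):62,rabbit:82):8):6,"
    "(dog:74,(pig:62,cow:62):12):22);"
)


# ---------------------------------------------------------------------------
# closed-form quantities

def lifetime_arithmetic() -> dict:
    """Half-life <-> mean-lifetime arithmetic for the reported estimates."""
    enh_ml = mean_lifetime(296.0)
    pro_ml = mean_lifetime(939.0)
    return {
        "enhancer_mean_lifetime": enh_ml,
        "promoter_mean_lifetime": pro_ml,
        "promoter_to_enhancer_lifetime_ratio": pro_ml / enh_ml,
        "lifetime_ratio_rounded": round(pro_ml / enh_ml),
    }


def printed_count_percentages() -> dict:
    """Percentage arithmetic over the highly-conserved element counts."""
    n_hc, n_hc_prom, n_hc_enh = 2151, 1871, 279
    n_prom, n_enh = 11838, 28963
    return {
        "pct_hc_promoter_of_hc": round(100 * n_hc_prom / n_hc),
        "pct_promoters_highly_conserved": round(100 * n_hc_prom / n_prom),
        "pct_enhancers_highly_conserved": round(100 * n_hc_enh / n_enh),
        "pct_all_regions_highly_conserved": round(100 * n_hc / (n_prom + n_enh)),
    }


# ---------------------------------------------------------------------------
# half-life recovery

def _panel_config(seed: int) -> SimConfig:
    return SimConfig(
        seed=seed, tree_newick=PANEL_TREE_NEWICK, n_blocks=12_000,
        n_root_elements={"promoter_dual": 5000, "promoter_k4": 0,
                         "enhancer": 5000},
        birth_rate={"promoter_dual": 0.0, "promoter_k4": 0.0, "enhancer": 0.0},
        half_life={"promoter_dual": 900.0, "promoter_k4": 900.0,
                   "enhancer": 300.0},
        replicate_overrides={}, n_genes=100, n_psg=10,
    )


def true_ratio_matrix(world, mark_class: str) -> pd.DataFrame:
    """Reciprocal-averaged conservation ratios from the true element
    histories (no peak-detection layer)."""
    el = world.elements
    blocks = el["block"].to_numpy()
    mask = (el["mark_class"] == mark_class).to_numpy()
    pres = world.presence
    sp = world.species
    mat = pd.DataFrame(1.0, index=sp, columns=sp)
    for i, a in enumerate(sp):
        for b in sp[i + 1:]:
            al = world.block_identity[a][blocks] == world.block_identity[b][blocks]
            ina = pres[a].to_numpy() & mask
            inb = pres[b].to_numpy() & mask
            ra = pres[b].to_numpy()[ina & al].mean()
            rb = pres[a].to_numpy()[inb & al].mean()
            mat.loc[a, b] = mat.loc[b, a] = (ra + rb) / 2
    return mat


def halflife_recovery(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Recover planted per-lineage half-lives (enhancer 300 Ma, promoter
    900 Ma) from pairwise conservation ratios on the 10-taxon panel.

    Conditioning each ratio on presence in the anchor species makes the
    pairwise ratio decay at the per-lineage loss rate, so the divergence-
    axis log-linear fit estimates the planted half-life directly.  Coverage
    uses the delete-one-species jackknife confidence interval.
    """
    planted = {"enhancer": 300.0, "promoter_dual": 900.0}
    cover = {"enhancer": 0, "promoter_dual": 0}
    estimates = {"enhancer": [], "promoter_dual": []}
    order_ok = 0
    for i in range(n_seeds):
        world = simulate_world(_panel_config(base_seed + i))
        fits = {}
        for klass in ("enhancer", "promoter_dual"):
            fit = fit_decay_jackknife(true_ratio_matrix(world, klass),
                                      world.tree)
            fits[klass] = fit
            estimates[klass].append(fit.half_life)
            cover[klass] += fit.ci_covers(planted[klass])
        order_ok += fits["promoter_dual"].half_life > fits["enhancer"].half_life
    return {
        "n_seeds": n_seeds,
        "enhancer_mean_estimate": float(np.mean(estimates["enhancer"])),
        "promoter_mean_estimate": float(np.mean(estimates["promoter_dual"])),
        "enhancer_ci_coverage": cover["enhancer"] / n_seeds,
        "promoter_ci_coverage": cover["promoter_dual"] / n_seeds,
        "promoter_gt_enhancer_runs": order_ok,
    }


# ---------------------------------------------------------------------------
# phylogeny recovery

def phylogeny_recovery(seed: int = 0) -> dict:
    """NJ on enhancer non-conservation distances recovers the generating
    topology; promoter distances with turnover disabled give a near-star
    matrix bounded by the technical noise floor."""
    world = simulate_world(SimConfig(seed=seed))
    cons = study.all_consensus(world)
    mat_e = study.class_ratio_matrix(world, cons, MarkClass.enhancer)
    rf = world.tree.unrooted_topology_distance(nj_tree(1.0 - mat_e))

    frozen = SimConfig(
        seed=seed,
        half_life={"promoter_dual": math.inf, "promoter_k4": math.inf,
                   "enhancer": 300.0},
        birth_rate={"promoter_dual": 0.0, "promoter_k4": 0.0, "enhancer": 1.2},
    )
    world2 = simulate_world(frozen)
    cons2 = study.all_consensus(world2)
    mat_p = study.class_ratio_matrix(world2, cons2, MarkClass.promoter_dual)
    d = (1.0 - mat_p).to_numpy()
    max_dist = float(d[~np.eye(len(d), dtype=bool)].max())
    return {"enhancer_rf_distance": float(rf),
            "promoter_max_pairwise_distance": max_dist}


# ---------------------------------------------------------------------------
# permutation-test calibration

def _random_call_table(rng, n_elements: int, species: list[str],
                       p_conserved: float) -> MarkCallTable:
    ids = pd.Index([f"e{i}" for i in range(n_elements)])
    conserved = {
        m: pd.DataFrame(rng.random((n_elements, len(species))) < p_conserved,
                        index=ids, columns=species)
        for m in MARKS
    }
    alignable = pd.DataFrame(True, index=ids, columns=species)
    return MarkCallTable(conserved, alignable)


def permutation_calibration(n_seeds: int = 200, n_iter: int = 1000,
                            n_elements: int = 1000, base_seed: int = 0) -> dict:
    """Null calibration (labels already exchangeable -> uniform p) and the
    planted deep-conservation lower bound p = 1/(n_iter + 1)."""
    species = ["s1", "s2", "s3", "s4"]
    panel = SpeciesPanel("ref", tuple(species), {})
    pvals = []
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + 10_000 + i)
        calls = _random_call_table(rng, n_elements, species, 0.6)
        rep = permutation_test_conserved_count(calls, panel, n_iter=n_iter,
                                               rng=rng)
        pvals.append(rep.p_value)
    ks = st.kstest(pvals, "uniform")

    # planted fixture: a block of elements conserved everywhere
    rng = np.random.default_rng(base_seed + 77)
    calls = _random_call_table(rng, n_elements, species, 0.2)
    for m in MARKS:
        calls.conserved[m].iloc[:200, :] = True
    rep = permutation_test_conserved_count(calls, panel, n_iter=n_iter, rng=rng)
    return {
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_seeds": n_seeds,
        "planted_p": rep.p_value,
        "planted_p_expected": 1.0 / (n_iter + 1),
        "planted_p_display": rep.p_display,
    }


# ---------------------------------------------------------------------------
# FDR calibration and the exact binomial oracle

def exact_binomial_tail(k: int, n: int, p_num: int, p_den: int) -> float:
    """P(Bin(n, p_num/p_den) >= k) by exact rational summation."""
    p = Fraction(p_num, p_den)
    q = 1 - p
    total = Fraction(0)
    for i in range(k, n + 1):
        total += math.comb(n, i) * p**i * q**(n - i)
    return float(total)


def fdr_calibration(n_sims: int = 500, n_families: int = 50,
                    base_seed: int = 0, alpha: float = 0.05) -> dict:
    """Realized FDR of the BH-corrected repeat enrichment under the null
    (foreground drawn from background rates), plus the worst absolute
    disagreement between the binomial p-values and an exact rational
    summation oracle."""
    rng = np.random.default_rng(base_seed + 40_000)
    fg_total, bg_total = 200, 2000
    fdp = []
    for _ in range(n_sims):
        bg_rates = rng.uniform(0.02, 0.3, n_families)
        bg_counts = {f"fam{j}": int(round(r * bg_total))
                     for j, r in enumerate(bg_rates)}
        fg_counts = {f"fam{j}": int(rng.binomial(fg_total,
                                                 bg_counts[f"fam{j}"] / bg_total))
                     for j in range(n_families)}
        res = repeat_enrichment(fg_counts, fg_total, bg_counts, bg_total)
        n_rej = sum(1 for r in res if r.q < alpha)
        fdp.append(1.0 if n_rej else 0.0)  # every rejection is false here
    fdp = np.array(fdp)
    realized_fdr = float(fdp.mean())
    se = float(fdp.std(ddof=1) / math.sqrt(n_sims))

    # oracle agreement on a spread of cases
    max_diff = 0.0
    for k, n, num, den in [(10, 100, 1, 10), (0, 100, 3, 10), (25, 80, 1, 5),
                           (3, 50, 1, 50), (40, 200, 3, 20)]:
        exact = exact_binomial_tail(k, n, num, den)
        approx = float(st.binom.sf(k - 1, n, num / den))
        max_diff = max(max_diff, abs(exact - approx))
    return {"realized_fdr": realized_fdr, "fdr_se": se, "alpha": alpha,
            "binomial_oracle_max_abs_diff": max_diff}


# ---------------------------------------------------------------------------
# brute-force oracle equivalence on randomized small instances

def _bruteforce_consensus(peaks: list[ReplicatePeak], min_replicates: int,
                          min_overlap: float) -> set[tuple[int, int]]:
    """Base-set reimplementation of the reproducibility + merge rule."""
    bases = [set(range(p.interval.start, p.interval.end)) for p in peaks]
    n = len(peaks)
    edges = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            ov = len(bases[i] & bases[j])
            if ov > 0 and ov >= min_overlap * min(len(bases[i]), len(bases[j])):
                edges[i][j] = edges[j][i] = True
    reproducible = []
    for i in range(n):
        partners = {peaks[j].replicate for j in range(n)
                    if edges[i][j] and peaks[j].replicate != peaks[i].replicate}
        if len(partners) >= min_replicates - 1:
            reproducible.append(i)
    seen, out = set(), set()
    for i in reproducible:
        if i in seen:
            continue
        comp, stack = [], [i]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            comp.append(u)
            stack.extend(v for v in reproducible if edges[u][v])
        span = set().union(*(bases[u] for u in comp))
        out.add((min(span), max(span) + 1))
    return out


def _oracle_consensus_trial(rng) -> bool:
    n_reps = int(rng.integers(2, 4))
    peaks = []
    for r in range(n_reps):
        for _ in range(int(rng.integers(1, 5))):
            s = int(rng.integers(0, 60))
            e = s + int(rng.integers(1, 25))
            peaks.append(ReplicatePeak(
                GenomicInterval("x", "c", s, e), "H3K27ac", f"r{r}",
                1.0 + float(rng.random())))
    min_ov = float(rng.choice([0.2, 0.5, 0.8]))
    got = build_consensus(peaks, n_replicates=n_reps, min_overlap=min_ov)
    want = _bruteforce_consensus(peaks, 2, min_ov)
    return {(c.interval.start, c.interval.end) for c in got} == want


def _oracle_conservation_trial(rng) -> bool:
    # random non-overlapping block map on one chromosome pair
    n_blocks = int(rng.integers(1, 5))
    cuts = np.sort(rng.choice(np.arange(1, 100), size=2 * n_blocks,
                              replace=False))
    rows = []
    t_cursor = int(rng.integers(0, 50))
    for b in range(n_blocks):
        s, e = int(cuts[2 * b]), int(cuts[2 * b + 1])
        gap = int(rng.integers(0, 40))
        rows.append(("A", "c", s, e, "+", "B", "c", t_cursor + gap,
                     t_cursor + gap + (e - s), "+"))
        t_cursor += gap + (e - s)
    omap = OrthologyMap(pd.DataFrame(rows, columns=[
        "species_a", "chrom_a", "start_a", "end_a", "strand_a",
        "species_b", "chrom_b", "start_b", "end_b", "strand_b"]))
    qs = int(rng.integers(0, 100))
    qe = qs + int(rng.integers(1, 30))
    region = GenomicInterval("A", "c", qs, qe)
    targets = []
    for _ in range(int(rng.integers(0, 4))):
        ts = int(rng.integers(0, 150))
        targets.append(GenomicInterval("B", "c", ts, ts + int(rng.integers(1, 40))))

    # base-level oracle
    mapped = []
    for base in range(qs, qe):
        for (_, _, s, e, _, _, _, tb, _, _) in rows:
            if s <= base < e:
                mapped.append(tb + (base - s))
                break
    if not mapped:
        want = "unalignable"
    else:
        mapped.sort()
        gaps = [b - a - 1 for a, b in zip(mapped, mapped[1:])]
        if gaps and max(gaps) > 2 * region.length:
            want = "unalignable"
        else:
            span = set(range(mapped[0], mapped[-1] + 1))
            best = max((len(span & set(range(t.start, t.end)))
                        for t in targets), default=0)
            want = "conserved" if best >= 0.5 * len(span) else "absent"
    from .orthomap import call_conservation
    got = call_conservation(region, omap, targets)
    return got == want


def _oracle_age_trial(rng, tree: SpeciesTree, skbio_tree) -> bool:
    from .age_repeats import sequence_age
    species = tree.species
    ref = str(rng.choice(species))
    status = {s: str(rng.choice(["unique", "split", "unmapped"], p=[.6, .2, .2]))
              for s in species if s != ref}
    age, cat = sequence_age(ref, status, tree)
    # oracle: patristic distance / 2 on an independently parsed tree
    want_age = 0.0
    for s, stat in status.items():
        if stat == "unique":
            d = skbio_tree.find(ref).distance(skbio_tree.find(s)) / 2.0
            want_age = max(want_age, d)
    want_cat = ("young" if want_age < 40 else
                "mid" if want_age < 100 else "ancestral")
    return abs(age - want_age) < 1e-9 and cat == want_cat


def _oracle_domain_trial(rng) -> bool:
    chrom_len = 4_000_000
    n_genes = int(rng.integers(1, 6))
    tss = np.sort(rng.choice(np.arange(10_000, chrom_len - 10_000, 1000),
                             size=n_genes, replace=False))
    strands = rng.choice(["+", "-"], size=n_genes)
    genes = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n_genes)],
                          "chrom": "c", "tss": tss, "strand": strands})
    models = build_regulatory_domains(genes, {"c": chrom_len})
    # oracle: direct rule arithmetic per gene
    basal = []
    for t, s in zip(tss, strands):
        b0, b1 = (t - 1000, t + 5000) if s == "-" else (t - 5000, t + 1000)
        basal.append((max(0, b0), min(chrom_len, b1)))
    ok = True
    for i, gm in enumerate(models):
        b0, b1 = basal[i]
        lefts = [e for j, (s, e) in enumerate(basal) if j != i and e <= b0]
        rights = [s for j, (s, e) in enumerate(basal) if j != i and s >= b1]
        want0 = max([max(0, b0 - 1_000_000)] + lefts)
        want1 = min([min(chrom_len, b1 + 1_000_000)] + rights)
        ok &= (gm.domain_start, gm.domain_end) == (want0, want1)
    # element association by >= 1 bp overlap
    from .gene_assoc import associate_elements
    els = {}
    for k in range(int(rng.integers(1, 6))):
        s = int(rng.integers(0, chrom_len - 5000))
        els[f"e{k}"] = GenomicInterval("x", "c", s, s + int(rng.integers(200, 3000)))
    links = associate_elements(els, models)
    got = set(map(tuple, links[["element_id", "gene_id"]].to_numpy()))
    want = set()
    for eid, iv in els.items():
        for gm in models:
            if min(iv.end, gm.domain_end) > max(iv.start, gm.domain_start):
                want.add((eid, gm.gene_id))
    return ok and got == want


def oracle_equivalence(n_instances: int = 1000, base_seed: int = 0) -> dict:
    """Randomized-instance equivalence of the interval machinery against
    brute-force base-set / rule-arithmetic oracles."""
    from skbio import TreeNode
    import io

    rng = np.random.default_rng(base_seed + 70_000)
    tree = SpeciesTree.default()
    skb = TreeNode.read(io.StringIO(tree.to_newick()),
                        convert_underscores=False)
    fails = {"consensus": 0, "conservation": 0, "age": 0, "domains": 0}
    for _ in range(n_instances):
        fails["consensus"] += not _oracle_consensus_trial(rng)
        fails["conservation"] += not _oracle_conservation_trial(rng)
        fails["age"] += not _oracle_age_trial(rng, tree, skb)
    for _ in range(max(1, n_instances // 5)):  # domain trials are slower
        fails["domains"] += not _oracle_domain_trial(rng)
    return {"n_instances": n_instances,
            "mismatches": fails,
            "total_mismatches": sum(fails.values())}


# ---------------------------------------------------------------------------
# end-to-end truth recovery on the default fixture

def _truth_exclusive_sets(world, reference: str, clade_members: list[str]):
    """True recently-evolved and lineage-specific element-id sets, defined
    over species where the element's DNA is alignable from the reference."""
    el = world.elements
    blocks = el["block"].to_numpy()
    pres = world.presence
    in_ref = pres[reference].to_numpy()
    present_alignable_outside = np.zeros(len(el), bool)
    outside_clade = np.zeros(len(el), bool)
    for s in world.species:
        if s == reference:
            continue
        al = (world.block_identity[reference][blocks]
              == world.block_identity[s][blocks])
        hit = pres[s].to_numpy() & al
        present_alignable_outside |= hit
        if s not in clade_members:
            outside_clade |= hit
    truth_recent = set(el.index[in_ref & ~present_alignable_outside])
    in_clade = in_ref.copy()
    for s in clade_members:
        in_clade &= pres[s].to_numpy()
    truth_lineage = set(el.index[in_clade & ~outside_clade])
    return truth_recent, truth_lineage


def _precision_recall(est: set, est_unmatched: int, truth: set):
    tp = len(est & truth)
    denom = len(est) + est_unmatched
    return (tp / denom if denom else float("nan"),
            tp / len(truth) if truth else float("nan"))


def end_to_end_truth_recovery(seed: int = 0) -> dict:
    """Run the full pipeline on the default fixture and score recently
    evolved / lineage-specific calls and age-category fractions against the
    generator's truth tables."""
    world = simulate_world(SimConfig(seed=seed))
    cons = study.all_consensus(world)
    calls, anchor_els = study.anchor_call_table(world, "human", cons)
    m2t = study.match_to_truth(world, "human", cons["human"])
    id2idx = {f"human_c{i}": i for i in range(len(cons["human"]))}

    primates = ["macaque", "vervet", "marmoset"]
    truth_recent, truth_lineage = _truth_exclusive_sets(world, "human", primates)

    recent = find_recently_evolved(
        calls, {e: anchor_els[e].mark_class.value for e in calls.elements})
    est_recent, unmatched_r = set(), 0
    for eid in recent.index:
        t = m2t[id2idx[eid]]
        if t is None:
            unmatched_r += 1
        else:
            est_recent.add(t)
    prec_r, rec_r = _precision_recall(est_recent, unmatched_r, truth_recent)

    lineage = find_lineage_specific(calls, primates)
    est_lin, unmatched_l = set(), 0
    for c in lineage:
        t = m2t[id2idx[c.element_id]]
        if t is None:
            unmatched_l += 1
        else:
            est_lin.add(t)
    prec_l, rec_l = _precision_recall(est_lin, unmatched_l, truth_lineage)

    # age categories vs configured birth placement.  Only terminal-branch
    # births carry an exact Bernoulli(frac_young) placement; older elements
    # that survived solely in the reference sit in ancestral DNA and would
    # dilute the comparison.
    terminal = [t for t in est_recent
                if world.elements.loc[t, "birth_node"] == "human"]
    young = sum(
        1 for t in terminal
        if age_category(world.true_sequence_age("human", t)) == "young")
    n_terminal = len(terminal)
    klasses = [world.elements.loc[t, "mark_class"] for t in terminal]
    expected_young = float(np.mean([
        world.config.frac_young_births[k] for k in klasses])) if klasses else 0.0
    return {
        "recent_precision": prec_r, "recent_recall": rec_r,
        "recent_n_truth": len(truth_recent),
        "lineage_precision": prec_l, "lineage_recall": rec_l,
        "lineage_n_truth": len(truth_lineage),
        "young_fraction": young / n_terminal if n_terminal else float("nan"),
        "young_fraction_expected": expected_young,
        "young_fraction_n": n_terminal,
        "young_fraction_se": math.sqrt(
            expected_young * (1 - expected_young) / n_terminal)
        if n_terminal else float("nan"),
    }


# ---------------------------------------------------------------------------
# PSG association power and calibration

def psg_power(n_seeds: int = 200, base_seed: int = 0,
              fold: float = 3.0) -> dict:
    """Power of the three PSG association tests under a planted 3x recent-
    enhancer rate, and null calibration of the link-level hypergeometric."""
    hits = np.zeros(3, int)
    for i in range(n_seeds):
        data = simulate_psg_links(n_genes=300, n_psg=40,
                                  mean_enhancers_per_gene=5.0,
                                  recent_rate=0.08, psg_fold=fold,
                                  seed=base_seed + 50_000 + i)
        res = psg_enrichment(data["links_all"], data["links_recent"],
                             data["universe"], data["psg"])
        hits += np.array([r.p < 0.05 for r in res])

    null_p = []
    for i in range(n_seeds):
        data = simulate_psg_links(n_genes=500, n_psg=50,
                                  mean_enhancers_per_gene=6.0,
                                  recent_rate=0.1, psg_fold=1.0,
                                  seed=base_seed + 60_000 + i)
        res = psg_enrichment(data["links_all"], data["links_recent"],
                             data["universe"], data["psg"])
        null_p.append(res[0].p)
    ks = st.kstest(null_p, "uniform")
    return {
        "n_seeds": n_seeds,
        "power_link_hypergeom": hits[0] / n_seeds,
        "power_gene_hypergeom": hits[1] / n_seeds,
        "power_wilcoxon": hits[2] / n_seeds,
        "null_ks_statistic": float(ks.statistic),
        "null_ks_pvalue": float(ks.pvalue),
    }
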
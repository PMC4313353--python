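"""Synthetic genome-evolution fixture generator with known ground truth.

The generator produces a complete miniature comparative-epigenomics study:
a dated species tree, per-species genomes, orthology maps, regulatory
elements with birth/loss histories, replicate ChIP-seq peak calls with
noise, repeat annotations, genes, an expression matrix and a list of
positively selected genes — all seeded and deterministic.

Model
-----
Each species' genome is a single chromosome tiled by fixed-size blocks.
DNA *alignability* evolves by block turnover along each branch: a block is
replaced by lineage-specific sequence with probability
``1 - exp(-t * ln2 / dna_half_life)`` over a branch of t Ma.  Two species
align at a block iff neither lineage replaced it since their split, so
orthology maps (runs of shared blocks) and sequence ages fall out of the
same process.

Regulatory-element *activity* evolves independently of alignability (so
"alignable but inactive" orthologs exist): each element survives a branch
with probability ``exp(-t * ln2 / half_life[class])`` (memoryless,
lineage-independent loss), and is forcibly lost when its underlying block
turns over.  New elements are born along branches at a per-class rate per
Ma, placed either in young DNA (blocks replaced on the same branch) or in
ancestral DNA (blocks at least 100 Ma old), with a per-class mixing
fraction — the knob that controls how much recent regulatory innovation is
exaptation of old sequence.

ChIP-seq noise is emulated at the peak level: every element present in a
species emits a peak per mark per replicate with probability
``peak_sensitivity``, with boundary jitter and multiplicative log-normal
intensity noise; false-positive peaks are sprinkled at random element-free
blocks.  Reproducibility of an element therefore *emerges* from detection
sampling rather than being assigned.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, MarkClass
from .orthomap import ORTHOMAP_COLUMNS, OrthologyMap
from .peaks import ReplicatePeak
from .phylo import DEFAULT_TREE_NEWICK, SpeciesTree

__all__ = ["SimConfig", "SyntheticWorld", "simulate_world", "emit_fixtures",
           "load_fixtures"]

LN2 = math.log(2.0)

CLASSES = (MarkClass.promoter_dual, MarkClass.promoter_k4, MarkClass.enhancer)

DEFAULT_REPEAT_FAMILIES = (
    # (repeat class, family, density per Mb, young-DNA placement weight)
    ("LINE", "L1", 18.0, 4.0),
    ("LINE", "L2", 10.0, 1.0),
    ("SINE", "AluY", 25.0, 6.0),
    ("SINE", "MIR", 14.0, 1.0),
    ("LTR", "ERV1", 8.0, 5.0),
    ("LTR", "ERVL", 6.0, 1.0),
    ("DNA", "hAT-Charlie", 7.0, 1.0),
    ("DNA", "TcMar-Tigger", 5.0, 1.0),
)

DEFAULT_TISSUES = ("liver", "brain", "heart", "kidney", "muscle", "testis")


@dataclass
class SimConfig:
    """Configuration of the synthetic study (all rates per Ma, lengths bp)."""

    seed: int = 0
    tree_newick: str = DEFAULT_TREE_NEWICK
    block_size: int = 1000
    n_blocks: int = 6000
    # element birth-death process
    n_root_elements: dict = field(default_factory=lambda: {
        "promoter_dual": 600, "promoter_k4": 200, "enhancer": 1000})
    half_life: dict = field(default_factory=lambda: {
        "promoter_dual": 900.0, "promoter_k4": 900.0, "enhancer": 300.0})
    birth_rate: dict = field(default_factory=lambda: {
        "promoter_dual": 0.25, "promoter_k4": 0.08, "enhancer": 1.2})
    frac_young_births: dict = field(default_factory=lambda: {
        "promoter_dual": 0.15, "promoter_k4": 0.15, "enhancer": 0.25})
    dna_half_life: float = 3000.0
    ancestral_min_age: float = 100.0
    element_length: dict = field(default_factory=lambda: {
        "promoter_dual": 600, "promoter_k4": 500, "enhancer": 500})
    # peak emulation
    n_replicates: int = 3
    replicate_overrides: dict = field(default_factory=lambda: {"whale": 1})
    peak_sensitivity: float = 0.95
    false_positive_rate: float = 0.02
    peak_jitter: int = 40
    intensity_meanlog: float = math.log(6.0)
    intensity_sdlog: float = 0.5
    replicate_sdlog: float = 0.3
    # annotations
    repeat_families: tuple = DEFAULT_REPEAT_FAMILIES
    repeat_length_range: tuple = (150, 600)
    n_genes: int = 300
    tissues: tuple = DEFAULT_TISSUES
    frac_tissue_specific: float = 0.4
    n_psg: int = 40
    psg_reference: str = "human"
    psg_association_strength: float = 1.0  # birth-weight multiplier near PSGs
    psg_window: int = 100_000
    coord_offset_step: int = 137

    def __post_init__(self) -> None:
        for d in (self.half_life,):
            for k, v in d.items():
                if v <= 0:
                    raise ValueError(f"half_life[{k}] must be > 0")
        for d in (self.birth_rate, self.frac_young_births):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"rate {k} must be >= 0")
        if self.dna_half_life <= 0:
            raise ValueError("dna_half_life must be > 0")
        if self.n_replicates < 1 or any(v < 1 for v in self.replicate_overrides.values()):
            raise ValueError("replicate counts must be >= 1")
        if not 0 < self.peak_sensitivity <= 1:
            raise ValueError("peak_sensitivity must be in (0, 1]")

    @property
    def genome_length(self) -> int:
        return self.block_size * self.n_blocks


def _surv(t: float, half_life: float) -> float:
    if math.isinf(half_life):
        return 1.0
    return math.exp(-t * LN2 / half_life)


class SyntheticWorld:
    """A realised synthetic study; see :func:`simulate_world`."""

    def __init__(self, config: SimConfig, tree: SpeciesTree):
        self.config = config
        self.tree = tree
        self.species: list[str] = tree.species
        self.chrom = "chr1"
        # filled by the simulator:
        self.block_identity: dict[str, np.ndarray] = {}
        self.identity_birth_age: np.ndarray | None = None
        self.elements: pd.DataFrame | None = None
        self.presence: pd.DataFrame | None = None  # elements x species (bool)
        self.replicate_peaks: dict[tuple[str, str], list[pd.DataFrame]] = {}
        self.repeats: dict[str, pd.DataFrame] = {}
        self.genes: pd.DataFrame | None = None
        self.expression: pd.DataFrame | None = None
        self.psg: list[str] = []
        self.constrained: dict[str, pd.DataFrame] = {}
        self._offsets = {s: i * config.coord_offset_step
                         for i, s in enumerate(self.species)}
        # anchor/reference species for genes, PSGs and constrained segments
        self.reference = (config.psg_reference
                          if config.psg_reference in self.species
                          else self.species[0])

    # -- coordinates -------------------------------------------------------
    def offset(self, species: str) -> int:
        return self._offsets[species]

    def block_interval(self, species: str, block: int) -> GenomicInterval:
        b = self.config.block_size
        off = self._offsets[species]
        return GenomicInterval(species, self.chrom, off + block * b, off + (block + 1) * b)

    def element_interval(self, species: str, idx: int) -> GenomicInterval:
        row = self.elements.iloc[idx]
        off = self._offsets[species]
        return GenomicInterval(species, self.chrom,
                               off + int(row.start), off + int(row.end))

    # -- truth accessors ---------------------------------------------------
    def element_intervals(self, species: str,
                          mark_class: MarkClass | None = None,
                          present_only: bool = True) -> dict[str, GenomicInterval]:
        """Truth element intervals in a species (ids -> intervals)."""
        df = self.elements
        keep = np.ones(len(df), bool)
        if present_only:
            keep &= self.presence[species].to_numpy()
        if mark_class is not None:
            keep &= (df["mark_class"] == mark_class.value).to_numpy()
        return {
            df.index[i]: self.element_interval(species, i)
            for i in np.nonzero(keep)[0]
        }

    def alignable(self, a: str, b: str) -> np.ndarray:
        """Boolean per block: does DNA align between the two species."""
        return self.block_identity[a] == self.block_identity[b]

    def true_conservation_set(self, element_id: str) -> set[str]:
        return set(self.presence.columns[self.presence.loc[element_id]])

    def true_sequence_age(self, reference: str, element_id: str) -> float:
        """Max divergence of a species whose DNA aligns at the element's block."""
        block = int(self.elements.loc[element_id, "block"])
        ref_ident = self.block_identity[reference][block]
        age = 0.0
        for s in self.species:
            if s == reference:
                continue
            if self.block_identity[s][block] == ref_ident:
                age = max(age, self.tree.divergence_time(reference, s))
        return age

    def truth_table(self, reference: str | None = None) -> pd.DataFrame:
        """Per-element truth: class, birth node/age, conservation set, and —
        when a reference species is given — the sequence-age category of the
        underlying DNA seen from that reference."""
        df = self.elements[["mark_class", "birth_node", "birth_age", "block"]].copy()
        pres = self.presence
        df["n_species_present"] = pres.sum(axis=1)
        df["conserved_species"] = [
            ",".join(sorted(pres.columns[pres.loc[eid]])) for eid in df.index
        ]
        df["generating_half_life"] = [
            self.config.half_life[c] for c in df["mark_class"]
        ]
        if reference is not None:
            from .age_repeats import age_category
            ages = [self.true_sequence_age(reference, eid) for eid in df.index]
            df["sequence_age"] = ages
            df["age_category"] = [age_category(a) for a in ages]
        return df

    # -- derived data ------------------------------------------------------
    def orthology_map(self, a: str, b: str) -> OrthologyMap:
        """Block-run orthology map between two species."""
        shared = self.alignable(a, b)
        if not shared.any():
            raise ValueError(f"no alignable blocks between {a} and {b}")
        # maximal runs of consecutive shared blocks
        d = np.diff(shared.astype(np.int8))
        starts = np.nonzero(np.concatenate([[shared[0]], d == 1]))[0]
        ends = np.nonzero(np.concatenate([d == -1, [shared[-1]]]))[0] + 1
        bsz = self.config.block_size
        off_a, off_b = self._offsets[a], self._offsets[b]
        df = pd.DataFrame({
            "species_a": a, "chrom_a": self.chrom,
            "start_a": starts * bsz + off_a, "end_a": ends * bsz + off_a,
            "strand_a": "+",
            "species_b": b, "chrom_b": self.chrom,
            "start_b": starts * bsz + off_b, "end_b": ends * bsz + off_b,
            "strand_b": "+",
        })
        return OrthologyMap(df)

    def replicate_peak_objects(self, species: str, mark: str) -> list[ReplicatePeak]:
        out = []
        for rep_i, df in enumerate(self.replicate_peaks[(species, mark)]):
            for r in df.itertuples(index=False):
                out.append(ReplicatePeak(
                    interval=GenomicInterval(species, r.chrom, int(r.start), int(r.end)),
                    mark=mark, replicate=f"rep{rep_i + 1}",
                    fold_enrichment=float(r.fold_enrichment),
                ))
        return out

    def n_replicates(self, species: str) -> int:
        return self.config.replicate_overrides.get(species, self.config.n_replicates)


def simulate_world(config: SimConfig) -> SyntheticWorld:
    """Run the generative model; deterministic given ``config.seed``."""
    tree = SpeciesTree.from_newick(config.tree_newick)
    if len(tree.species) < 2:
        raise ValueError("tree must contain at least two species")
    world = SyntheticWorld(config, tree)
    rng = np.random.default_rng(config.seed)
    nb = config.n_blocks

    # ---- genes first (element births may be steered toward PSG domains)
    _simulate_genes(world, rng)
    psg_blocks = _psg_proximal_blocks(world)

    # ---- co-simulate DNA blocks and elements down the tree
    ident_root = np.arange(nb, dtype=np.int64)
    birth_ages = [tree.depth] * nb  # identity id -> age of origin (Ma)
    next_ident = nb

    class_names = [c.value for c in CLASSES]
    reg_class: list[str] = []
    reg_block: list[int] = []
    reg_birth_node: list[str] = []
    reg_birth_age: list[float] = []
    used = np.zeros(nb, bool)

    def new_root_elements() -> np.ndarray:
        total = sum(config.n_root_elements.get(c, 0) for c in class_names)
        if total > nb:
            raise ValueError("n_blocks too small for root elements")
        blocks = rng.choice(nb, size=total, replace=False)
        used[blocks] = True
        pos = 0
        for cname in class_names:
            k = config.n_root_elements.get(cname, 0)
            for b in blocks[pos:pos + k]:
                reg_class.append(cname)
                reg_block.append(int(b))
                reg_birth_node.append("root")
                reg_birth_age.append(tree.depth)
            pos += k
        return np.arange(total, dtype=np.int64)

    alive_root = new_root_elements()
    # per-leaf arrays of registry indices of elements present there
    presence_idx: dict[str, np.ndarray] = {}
    node_label = {}  # node -> stable label for birth bookkeeping

    def label_of(node) -> str:
        if node not in node_label:
            if node.is_leaf():
                node_label[node] = node.taxon.label
            elif node is tree.root:
                node_label[node] = "root"
            else:
                node_label[node] = "node_" + "|".join(sorted(tree.clade_species(node)))
        return node_label[node]

    def walk(node, ident: np.ndarray, alive: np.ndarray) -> None:
        """``alive`` holds registry *indices* of elements present at ``node``
        (positional booleans would misalign once sibling subtrees append
        births to the shared registry)."""
        nonlocal next_ident
        if node.is_leaf():
            world.block_identity[node.taxon.label] = ident
            presence_idx[node.taxon.label] = alive
            return
        for child in node.child_nodes():
            t = float(child.edge.length or 0.0)
            # DNA turnover
            p_keep = _surv(t, config.dna_half_life)
            turned = rng.random(nb) >= p_keep
            ident_c = ident.copy()
            n_new = int(turned.sum())
            if n_new:
                ident_c[turned] = np.arange(next_ident, next_ident + n_new)
                parent_age = tree.node_age(node)
                birth_ages.extend([parent_age] * n_new)
                next_ident += n_new
            # activity loss + forced loss with the underlying DNA
            alive_c = alive
            if alive_c.size:
                cls_arr = np.array([reg_class[i] for i in alive_c])
                p = np.empty(alive_c.size)
                for cname in class_names:
                    p[cls_arr == cname] = _surv(t, config.half_life[cname])
                survive = rng.random(alive_c.size) < p
                blocks_arr = np.array([reg_block[i] for i in alive_c])
                alive_c = alive_c[survive & ~turned[blocks_arr]]
            # births along the branch
            child_lab = label_of(child)
            is_ref_terminal = (child.is_leaf()
                               and child.taxon.label == world.reference)
            born_idx = []
            for cname in class_names:
                rate = config.birth_rate.get(cname, 0.0)
                n_birth = rng.poisson(rate * t) if rate * t > 0 else 0
                for _ in range(n_birth):
                    young = rng.random() < config.frac_young_births.get(cname, 0.0)
                    block = _pick_birth_block(
                        rng, used, turned, np.array(birth_ages), ident_c,
                        config, young,
                        psg_blocks if (is_ref_terminal
                                       and cname == "enhancer") else None,
                    )
                    if block is None:
                        continue
                    used[block] = True
                    born_idx.append(len(reg_class))
                    reg_class.append(cname)
                    reg_block.append(int(block))
                    reg_birth_node.append(child_lab)
                    reg_birth_age.append(tree.node_age(node))
            if born_idx:
                alive_c = np.concatenate(
                    [alive_c, np.array(born_idx, np.int64)])
            walk(child, ident_c, alive_c)

    walk(tree.root, ident_root, alive_root)
    world.identity_birth_age = np.array(birth_ages)

    # ---- element registry, coordinates, intensities
    n_el = len(reg_class)
    ids = [f"e{i:05d}" for i in range(n_el)]
    lengths = np.array([config.element_length[c] for c in reg_class])
    jitter = config.peak_jitter
    pad_max = config.block_size - lengths - jitter
    pads = jitter + (rng.random(n_el) * (pad_max - jitter)).astype(np.int64)
    starts = np.asarray(reg_block) * config.block_size + pads
    elements = pd.DataFrame({
        "mark_class": reg_class,
        "block": reg_block,
        "start": starts,
        "end": starts + lengths,
        "birth_node": reg_birth_node,
        "birth_age": reg_birth_age,
        "intensity": np.exp(rng.normal(config.intensity_meanlog,
                                       config.intensity_sdlog, n_el)),
    }, index=pd.Index(ids, name="element_id"))
    world.elements = elements
    pres_cols = {}
    for s in world.species:
        col = np.zeros(n_el, bool)
        col[presence_idx[s]] = True
        pres_cols[s] = col
    world.presence = pd.DataFrame(pres_cols, index=elements.index)

    # ---- replicate peaks
    _simulate_peaks(world, rng, used)

    # ---- repeats, expression, constrained elements
    for s in world.species:
        world.repeats[s] = _simulate_repeats(world, s, rng)
    _simulate_expression(world, rng)
    world.constrained[world.reference] = _simulate_constrained(
        world, world.reference, rng)
    return world


def _pick_birth_block(rng, used, turned, birth_ages_arr, ident_c, config,
                      young: bool, psg_blocks: np.ndarray | None):
    """Choose an unused block for a newborn element (young vs ancestral DNA)."""
    block_age = birth_ages_arr[ident_c]
    if young:
        cand = np.nonzero(turned & ~used)[0]
        if cand.size == 0:  # no fresh DNA left on this branch
            cand = np.nonzero((block_age >= config.ancestral_min_age) & ~used)[0]
    else:
        cand = np.nonzero((block_age >= config.ancestral_min_age) & ~used)[0]
        if cand.size == 0:
            cand = np.nonzero(~used)[0]
    if cand.size == 0:
        return None
    if psg_blocks is not None and config.psg_association_strength != 1.0:
        w = np.ones(cand.size)
        w[np.isin(cand, psg_blocks)] = config.psg_association_strength
        w /= w.sum()
        return int(rng.choice(cand, p=w))
    return int(rng.choice(cand))


def _simulate_peaks(world: SyntheticWorld, rng, used_blocks: np.ndarray) -> None:
    cfg = world.config
    el = world.elements
    free_blocks = np.nonzero(~used_blocks)[0]
    for s in world.species:
        off = world.offset(s)
        present = world.presence[s].to_numpy()
        nreps = world.n_replicates(s)
        for mark in ("H3K4me3", "H3K27ac"):
            has_mark = np.array([mark in MarkClass(c).marks
                                 for c in el["mark_class"]])
            idx = np.nonzero(present & has_mark)[0]
            reps = []
            for _ in range(nreps):
                detected = idx[rng.random(idx.size) < cfg.peak_sensitivity]
                st = (el["start"].to_numpy()[detected] + off
                      - rng.integers(0, cfg.peak_jitter + 1, detected.size))
                en = (el["end"].to_numpy()[detected] + off
                      + rng.integers(0, cfg.peak_jitter + 1, detected.size))
                fold = (el["intensity"].to_numpy()[detected]
                        * np.exp(rng.normal(0.0, cfg.replicate_sdlog, detected.size)))
                name = el.index.to_numpy()[detected]
                # false positives on element-free blocks
                n_fp = rng.poisson(cfg.false_positive_rate * idx.size)
                if n_fp and free_blocks.size:
                    fb = rng.choice(free_blocks, size=n_fp)
                    flen = rng.integers(300, 700, n_fp)
                    fpos = rng.integers(0, cfg.block_size - flen)
                    fst = fb * cfg.block_size + fpos + off
                    st = np.concatenate([st, fst])
                    en = np.concatenate([en, fst + flen])
                    fold = np.concatenate([
                        fold, np.exp(rng.normal(math.log(3.0), 0.4, n_fp))])
                    name = np.concatenate([name, np.array([f"fp_{i}" for i in range(n_fp)])])
                df = pd.DataFrame({
                    "chrom": world.chrom, "start": st, "end": en,
                    "name": name, "score": 0, "strand": ".",
                    "fold_enrichment": np.round(fold, 4),
                }).sort_values(["start", "end"]).reset_index(drop=True)
                reps.append(df)
            world.replicate_peaks[(s, mark)] = reps


def _simulate_repeats(world: SyntheticWorld, species: str, rng) -> pd.DataFrame:
    cfg = world.config
    genome_mb = cfg.genome_length / 1e6
    block_age = world.identity_birth_age[world.block_identity[species]]
    young = block_age < 40.0
    rows = []
    lo, hi = cfg.repeat_length_range
    for rclass, family, density, young_weight in cfg.repeat_families:
        n = rng.poisson(density * genome_mb)
        if n == 0:
            continue
        w = np.where(young, young_weight, 1.0).astype(float)
        w /= w.sum()
        blocks = rng.choice(cfg.n_blocks, size=n, p=w)
        lengths = rng.integers(lo, hi + 1, n)
        lengths = np.minimum(lengths, cfg.block_size)
        pos = rng.integers(0, cfg.block_size - lengths + 1)
        st = blocks * cfg.block_size + pos + world.offset(species)
        for i in range(n):
            rows.append((world.chrom, int(st[i]), int(st[i] + lengths[i]),
                         f"{family}_{len(rows)}", 0,
                         "+" if rng.random() < 0.5 else "-", rclass, family))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score",
                                     "strand", "repeat_class", "repeat_family"])
    return df.sort_values(["start", "end"]).reset_index(drop=True)


def _simulate_genes(world: SyntheticWorld, rng) -> None:
    cfg = world.config
    tss = np.sort(rng.choice(cfg.genome_length, size=cfg.n_genes, replace=False))
    strand = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    world.genes = pd.DataFrame({
        "gene_id": [f"g{i:04d}" for i in range(cfg.n_genes)],
        "chrom": world.chrom,
        "tss": tss,
        "strand": strand,
    })
    world.psg = sorted(rng.choice(world.genes["gene_id"].to_numpy(),
                                  size=cfg.n_psg, replace=False).tolist())


def _psg_proximal_blocks(world: SyntheticWorld) -> np.ndarray:
    cfg = world.config
    psg_tss = world.genes.set_index("gene_id").loc[world.psg, "tss"].to_numpy()
    centers = (np.arange(cfg.n_blocks) + 0.5) * cfg.block_size
    near = np.zeros(cfg.n_blocks, bool)
    for t in psg_tss:
        near |= np.abs(centers - t) <= cfg.psg_window
    return np.nonzero(near)[0]


def _simulate_expression(world: SyntheticWorld, rng) -> None:
    cfg = world.config
    tissues = list(cfg.tissues)
    n = cfg.n_genes
    specific = rng.random(n) < cfg.frac_tissue_specific
    assigned = rng.integers(0, len(tissues), n)
    mat = np.exp(rng.normal(math.log(15.0), 0.4, (n, len(tissues))))
    for j in range(len(tissues)):
        sel = specific & (assigned == j)
        mat[sel, :] = np.exp(rng.normal(math.log(1.5), 0.8, (sel.sum(), len(tissues))))
        mat[sel, j] = np.exp(rng.normal(math.log(40.0), 0.5, sel.sum()))
    world.expression = pd.DataFrame(
        np.round(mat, 3), index=world.genes["gene_id"], columns=tissues)


def _simulate_constrained(world: SyntheticWorld, species: str, rng) -> pd.DataFrame:
    """Constrained (purifying-selection) segments: enriched inside promoters,
    sparse inside enhancers, rare in background DNA."""
    cfg = world.config
    el = world.elements
    present = world.presence[species].to_numpy()
    off = world.offset(species)
    rows = []
    prob = {"promoter_dual": 0.6, "promoter_k4": 0.5, "enhancer": 0.15}
    for i in np.nonzero(present)[0]:
        row = el.iloc[i]
        if rng.random() < prob[row.mark_class]:
            length = int(rng.integers(80, 300))
            start = int(row.start) + int(rng.integers(0, int(row.end - row.start) - 79))
            rows.append((world.chrom, start + off,
                         min(start + length, int(row.end)) + off))
    n_bg = rng.poisson(0.02 * cfg.n_blocks)
    bg_blocks = rng.choice(cfg.n_blocks, size=n_bg, replace=False)
    for b in bg_blocks:
        length = int(rng.integers(80, 300))
        pos = int(rng.integers(0, cfg.block_size - length))
        st = b * cfg.block_size + pos + off
        rows.append((world.chrom, st, st + length))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.sort_values(["start", "end"]).reset_index(drop=True)


def simulate_psg_links(
    n_genes: int = 500,
    n_psg: int = 50,
    mean_enhancers_per_gene: float = 6.0,
    recent_rate: float = 0.1,
    psg_fold: float = 1.0,
    seed: int = 0,
) -> dict:
    """Light-weight generator of enhancer–gene link tables for calibrating
    the positively-selected-gene association tests.

    Each gene receives a Poisson number of enhancer links; each link is
    independently "recently evolved" at ``recent_rate``, multiplied by
    ``psg_fold`` for PSGs (1.0 = null, no association).  Returns dict with
    ``links_all``, ``links_recent`` (element_id/gene_id frames),
    ``universe`` and ``psg``.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    psg = sorted(rng.choice(genes, size=n_psg, replace=False).tolist())
    is_psg = np.isin(genes, psg)
    counts = rng.poisson(mean_enhancers_per_gene, n_genes)
    rate = np.where(is_psg, min(1.0, recent_rate * psg_fold), recent_rate)
    rows_all, rows_recent = [], []
    eid = 0
    for g, c, r in zip(genes, counts, rate):
        recent = rng.random(c) < r
        for j in range(c):
            rows_all.append((f"e{eid}", g))
            if recent[j]:
                rows_recent.append((f"e{eid}", g))
            eid += 1
    links_all = pd.DataFrame(rows_all, columns=["element_id", "gene_id"])
    links_recent = pd.DataFrame(rows_recent, columns=["element_id", "gene_id"])
    return {"links_all": links_all, "links_recent": links_recent,
            "universe": genes, "psg": psg}


# ---------------------------------------------------------------------------
# fixture emission / loading


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def emit_fixtures(world: SyntheticWorld, outdir) -> dict:
    """Write the whole study to plain-text files; returns a checksum manifest."""
    outdir = str(outdir)
    paths = []

    def _write(relpath: str, writer) -> None:
        path = os.path.join(outdir, relpath)
        os.makedirs(os.path.dirname(path), exist_ok=True)
        writer(path)
        paths.append(relpath)

    _write("tree.nwk", lambda p: open(p, "w").write(world.tree.to_newick() + "\n"))
    for (s, mark), reps in sorted(world.replicate_peaks.items()):
        for i, df in enumerate(reps):
            _write(f"peaks/{s}.{mark}.rep{i + 1}.bed",
                   lambda p, df=df: df.to_csv(p, sep="\t", header=False, index=False))
    sp = world.species
    for i, a in enumerate(sp):
        for b in sp[i + 1:]:
            omap = world.orthology_map(a, b)
            _write(f"orthology/{a}__{b}.tsv", omap.write_tsv)
    for s in sp:
        _write(f"repeats/{s}.bed",
               lambda p, s=s: world.repeats[s].to_csv(p, sep="\t", header=False,
                                                      index=False))
    _write("genes.tsv", lambda p: world.genes.to_csv(p, sep="\t", index=False))
    _write("expression.tsv", lambda p: world.expression.to_csv(p, sep="\t"))
    _write("psg.txt", lambda p: open(p, "w").write("\n".join(world.psg) + "\n"))
    for s, df in sorted(world.constrained.items()):
        _write(f"constrained/{s}.bed",
               lambda p, df=df: df.to_csv(p, sep="\t", header=False, index=False))
    _write("truth/elements.tsv",
           lambda p: world.truth_table().to_csv(p, sep="\t"))
    _write("truth/presence.tsv",
           lambda p: world.presence.astype(int).to_csv(p, sep="\t"))

    manifest = {
        "seed": world.config.seed,
        "n_species": len(sp),
        "files": {rel: _sha256(os.path.join(outdir, rel)) for rel in sorted(paths)},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


@dataclass
class FixtureSet:
    """In-memory view of an emitted fixture directory."""

    tree: SpeciesTree
    replicate_peaks: dict
    orthology: dict
    repeats: dict
    genes: pd.DataFrame
    expression: pd.DataFrame
    psg: list
    truth_elements: pd.DataFrame
    presence: pd.DataFrame


def load_fixtures(outdir) -> FixtureSet:
    outdir = str(outdir)
    tree = SpeciesTree.from_file(os.path.join(outdir, "tree.nwk"))
    peaks: dict[tuple[str, str], list[pd.DataFrame]] = {}
    pk_dir = os.path.join(outdir, "peaks")
    for fn in sorted(os.listdir(pk_dir)):
        s, mark, rep = fn[:-4].rsplit(".", 2)
        df = pd.read_csv(os.path.join(pk_dir, fn), sep="\t", header=None,
                         names=["chrom", "start", "end", "name", "score",
                                "strand", "fold_enrichment"])
        peaks.setdefault((s, mark), []).append(df)
    orth = {}
    od = os.path.join(outdir, "orthology")
    for fn in sorted(os.listdir(od)):
        a, b = fn[:-4].split("__")
        orth[(a, b)] = OrthologyMap.read_tsv(os.path.join(od, fn))
    repeats = {}
    rd = os.path.join(outdir, "repeats")
    for fn in sorted(os.listdir(rd)):
        repeats[fn[:-4]] = pd.read_csv(
            os.path.join(rd, fn), sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand",
                   "repeat_class", "repeat_family"])
    genes = pd.read_csv(os.path.join(outdir, "genes.tsv"), sep="\t")
    expr = pd.read_csv(os.path.join(outdir, "expression.tsv"), sep="\t",
                       index_col=0)
    with open(os.path.join(outdir, "psg.txt")) as fh:
        psg = [l.strip() for l in fh if l.strip()]
    truth = pd.read_csv(os.path.join(outdir, "truth", "elements.tsv"),
                        sep="\t", index_col=0)
    pres = pd.read_csv(os.path.join(outdir, "truth", "presence.tsv"),
                       sep="\t", index_col=0).astype(bool)
    return FixtureSet(tree, peaks, orth, repeats, genes, expr, psg, truth, pres)
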
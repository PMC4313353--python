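"""Dated species trees and divergence-time arithmetic.

The tree is rooted, with branch lengths in millions of years (Ma).  The
divergence time of two species is the *age of their most recent common
ancestor* — the one-way time back to the split, not the round-trip patristic
distance.  For an ultrametric tree of depth 180 Ma, a root-spanning pair
therefore has divergence 180.
"""

from __future__ import annotations

import io
from functools import cached_property

import dendropy
import numpy as np
import pandas as pd

__all__ = ["SpeciesTree", "DEFAULT_TREE_NEWICK"]

# Default 20-taxon fixture: a plausible dated mammalian phylogeny with two
# marsupial outgroups, root at 180 Ma, tip pairs from 13 Ma (macaque/vervet)
# to 180 Ma (eutherian vs marsupial).
DEFAULT_TREE_NEWICK = (
    "((((((human:29,(macaque:13,vervet:13):16):14,marmoset:43):39,"
    "tree_shrew:82):8,(((mouse:20,rat:20):53,"
    "(guinea_pig:41,naked_mole_rat:41):32):9,rabbit:82):8):6,"
    "(horse:78,(((dog:46,ferret:46):9,cat:55):19,"
    "(pig:62,(cow:56,(dolphin:34,whale:34):22):6):12):4):18):84,"
    "(opossum:80,tasmanian_devil:80):100);"
)


class SpeciesTree:
    """A rooted, dated (ultrametric within tolerance) species tree."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._node_age: dict[dendropy.Node, float] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self._node_age[node] = 0.0
            else:
                self._node_age[node] = max(
                    self._node_age[c] + (c.edge.length or 0.0)
                    for c in node.child_nodes()
                )
        self._leaf = {t.taxon.label: t for t in tree.leaf_node_iter()}

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        if len(tree.leaf_nodes()) < 2:
            raise ValueError("species tree must have at least two taxa")
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @classmethod
    def default(cls) -> "SpeciesTree":
        return cls.from_newick(DEFAULT_TREE_NEWICK)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- queries ----------------------------------------------------------
    @cached_property
    def species(self) -> list[str]:
        """Leaf labels in tree order."""
        return [t.taxon.label for t in self._tree.leaf_node_iter()]

    @property
    def depth(self) -> float:
        """Age of the root in Ma."""
        return self._node_age[self._tree.seed_node]

    def node_age(self, node: dendropy.Node) -> float:
        return self._node_age[node]

    def _require(self, label: str) -> dendropy.Node:
        try:
            return self._leaf[label]
        except KeyError:
            raise KeyError(f"unknown species {label!r}") from None

    def divergence_time(self, a: str, b: str) -> float:
        """Age in Ma of the most recent common ancestor of ``a`` and ``b``."""
        if a == b:
            self._require(a)
            return 0.0
        na, nb = self._require(a), self._require(b)
        ancestors_a = set()
        node = na
        while node is not None:
            ancestors_a.add(node)
            node = node.parent_node
        node = nb
        while node not in ancestors_a:
            node = node.parent_node
        return self._node_age[node]

    @cached_property
    def divergence_matrix(self) -> pd.DataFrame:
        """Symmetric species × species matrix of MRCA ages (Ma)."""
        sp = self.species
        mat = pd.DataFrame(0.0, index=sp, columns=sp)
        for i, a in enumerate(sp):
            for b in sp[i + 1:]:
                d = self.divergence_time(a, b)
                mat.loc[a, b] = mat.loc[b, a] = d
        return mat

    def clade_species(self, node: dendropy.Node) -> list[str]:
        return [t.taxon.label for t in node.leaf_iter()]

    def iter_edges(self):
        """Yield ``(parent, child, parent_age, child_age)`` in preorder.

        The root itself (no parent edge) is not yielded.
        """
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            yield (
                node.parent_node,
                node,
                self._node_age[node.parent_node],
                self._node_age[node],
            )

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depths = []
        for leaf in self._tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths.append(d)
        return max(depths) - min(depths) <= tol

    def unrooted_topology_distance(self, other_newick: str) -> float:
        """Robinson–Foulds distance between this topology and another newick."""
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=self.to_newick(), schema="newick",
                               taxon_namespace=tns, preserve_underscores=True)
        t2 = dendropy.Tree.get(data=other_newick, schema="newick",
                               taxon_namespace=tns, preserve_underscores=True)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        return dendropy.calculate.treecompare.symmetric_difference(t1, t2)
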
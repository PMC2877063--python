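"""Thin phylogenetic-tree layer over dendropy: newick I/O plus the array
form consumed by the likelihood and simulation machinery.

A tree is held as a dendropy ``Tree``; :class:`TreeArrays` flattens it into
postorder parent/child index arrays so pruning and sequence simulation are
plain numpy loops.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


@dataclass
class PhyloTree:
    """A rooted or unrooted tree with optional branch lengths."""

    tree: dendropy.Tree
    rooted: bool = False

    @classmethod
    def from_newick(cls, newick: str, rooted: bool = False) -> "PhyloTree":
        try:
            t = dendropy.Tree.get(
                data=newick, schema="newick",
                rooting="force-rooted" if rooted else "default-unrooted",
                suppress_internal_node_taxa=False,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise TreeError(f"newick parse failure: {exc}") from exc
        labels = [lf.taxon.label for lf in t.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate taxon labels")
        for e in t.edges():
            if e.length is not None and e.length < 0:
                raise TreeError("negative branch length")
        return cls(tree=t, rooted=rooted)

    @classmethod
    def read(cls, path: str | Path, rooted: bool = False) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text(), rooted=rooted)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.as_newick() + "\n")

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, real_value_format_specifier=".10g"
        ).strip()

    @property
    def taxa(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def n_taxa(self) -> int:
        return len(self.tree.leaf_nodes())

    def clone(self) -> "PhyloTree":
        return PhyloTree(tree=self.tree.clone(depth=1), rooted=self.rooted)


@dataclass
class TreeArrays:
    """Postorder flattened tree.

    Nodes 0..n_tips-1 are tips (in ``tip_labels`` order); internal nodes
    follow; the root is the last node.  ``postorder`` lists non-root nodes
    child-before-parent; ``parent[i]`` is the parent index; ``blen[i]`` the
    length of the branch above node i (root entry unused, 0).
    """

    tip_labels: list[str]
    parent: np.ndarray
    postorder: np.ndarray
    blen: np.ndarray
    node_labels: list[str | None]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def children(self, node: int) -> list[int]:
        return [i for i in range(self.n_nodes - 1) if self.parent[i] == node]


def tree_to_arrays(ptree: PhyloTree) -> TreeArrays:
    """Flatten a tree into postorder arrays (multifurcations allowed).

    Unrooted trees are handled by treating dendropy's internal rooting as a
    virtual root; under reversible models the likelihood is root-invariant.
    """
    t = ptree.tree
    nodes = list(t.postorder_node_iter())
    tips = [n for n in nodes if n.is_leaf()]
    internals = [n for n in nodes if not n.is_leaf()]
    order = tips + internals  # root (last postorder internal) ends up last
    index = {id(n): i for i, n in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=int)
    blen = np.zeros(n)
    labels: list[str | None] = []
    for node in order:
        i = index[id(node)]
        if node.parent_node is not None:
            parent[i] = index[id(node.parent_node)]
            blen[i] = node.edge.length if node.edge.length is not None else 0.0
        if node.is_leaf():
            labels.append(node.taxon.label)
        else:
            labels.append(node.taxon.label if node.taxon else getattr(node, "label", None))
    postorder = np.array(
        [index[id(node)] for node in nodes if node.parent_node is not None], dtype=int
    )
    return TreeArrays(
        tip_labels=[n.taxon.label for n in tips],
        parent=parent,
        postorder=postorder,
        blen=blen,
        node_labels=labels,
    )


def structurally_equal(a: PhyloTree, b: PhyloTree, tol: float = 1e-9) -> bool:
    """Same leaf-set bipartitions and branch lengths (up to tol)."""
    ta, tb = a.tree.clone(depth=1), b.tree.clone(depth=1)
    tns = dendropy.TaxonNamespace()
    ta.migrate_taxon_namespace(tns)
    tb.migrate_taxon_namespace(tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    ea = {bp.split_bitmask: e.length for e in ta.edges() if e.bipartition for bp in [e.bipartition]}
    eb = {bp.split_bitmask: e.length for e in tb.edges() if e.bipartition for bp in [e.bipartition]}
    if set(ea) != set(eb):
        return False
    for k in ea:
        la, lb = ea[k], eb[k]
        if (la is None) != (lb is None):
            return False
        if la is not None and abs(la - lb) > tol:
            return False
    return True
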
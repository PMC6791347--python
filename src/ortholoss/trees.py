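"""Rooted species trees with per-branch category labels.

Wraps :mod:`dendropy` trees.  Each branch (identified with its child
node) carries a category label used by the branch dN/dS model; branches
without an explicit label belong to the background category.  Labels are
read from and written to codeml-style ``#tag`` suffixes in Newick
strings, e.g. ``((A#fg:0.1,B:0.2)#fg:0.05,C:0.3);``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import dendropy

BACKGROUND = "background"


class TreeError(ValueError):
    pass


@dataclass
class LabeledTree:
    """Rooted tree whose branches carry category labels.

    Categories partition the branches: every branch has exactly one
    label (default :data:`BACKGROUND`).
    """

    tree: dendropy.Tree
    leaf_status: dict[str, str] = field(default_factory=dict)

    # -- construction ---------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "LabeledTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        tree.is_rooted = True
        for nd in tree:
            label = nd.taxon.label if nd.taxon is not None else nd.label
            cat = BACKGROUND
            if label and "#" in label:
                base, cat = label.split("#", 1)
                cat = cat or BACKGROUND
                if nd.taxon is not None:
                    nd.taxon.label = base
                else:
                    nd.label = base or None
            nd.edge.category = cat
        return cls(tree=tree)

    def copy(self) -> "LabeledTree":
        return LabeledTree.from_newick(self.to_newick())

    # -- queries --------------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def categories(self) -> list[str]:
        cats: list[str] = []
        for nd in self.tree:
            if nd.parent_node is None:
                continue
            c = getattr(nd.edge, "category", BACKGROUND)
            if c not in cats:
                cats.append(c)
        return cats

    def branches(self) -> list[dendropy.Node]:
        """Non-root nodes; each identifies the branch above it."""
        return [nd for nd in self.tree if nd.parent_node is not None]

    def mrca(self, taxa: Iterable[str]) -> dendropy.Node:
        taxa = list(taxa)
        if len(taxa) == 1:
            return self.tree.find_node_with_taxon_label(taxa[0])
        node = self.tree.mrca(taxon_labels=taxa)
        if node is None:
            raise TreeError(f"taxa not in tree: {taxa}")
        return node

    def clade_leaves(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def set_category(self, node: dendropy.Node, category: str) -> None:
        node.edge.category = category

    # -- serialization --------------------------------------------------
    def to_newick(self, tags: bool = True) -> str:
        t = self.tree.clone(depth=1)
        for nd in t:
            if nd.parent_node is None:
                continue
            cat = getattr(nd.edge, "category", BACKGROUND)
            if not tags or cat == BACKGROUND:
                continue
            if nd.taxon is not None:
                nd.taxon = dendropy.Taxon(label=f"{nd.taxon.label}#{cat}")
            else:
                nd.label = f"{nd.label or ''}#{cat}"
        s = t.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_leaf_node_labels=False,
        )
        return s.strip()


def balanced_tree(n_leaves: int, branch_length: float = 0.1) -> str:
    """Newick for a pectinate-balanced mix rooted tree with ``n_leaves``
    leaves named t1..tN and uniform branch lengths (used by simulations)."""
    names = [f"t{i+1}" for i in range(n_leaves)]

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"{names[lo]}:{branch_length}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{branch_length}"

    inner = build(0, n_leaves)
    # strip the root's own branch length
    return inner.rsplit(":", 1)[0] + ";"
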
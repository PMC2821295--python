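"""Phylogenetic tree container shared by the simulator and evaluation code.

A :class:`PhyloTree` is a rooted representation of a (usually unrooted)
binary tree: leaf nodes carry taxon labels, edges carry branch lengths in
expected substitutions per site.  Unrooted semantics apply throughout —
bipartitions are orientation-free and a degree-2 root is suppressed when
the tree is interpreted as unrooted.

Newick serialization is a small writer here; parsing goes through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import dendropy


@dataclass
class TreeNode:
    label: str | None = None
    length: float = 0.0  # length of the edge above this node
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted container for an (unrooted) phylogenetic tree."""

    def __init__(self, root: TreeNode):
        self.root = root
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels are not unique")

    # -- traversal ---------------------------------------------------------

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def edges(self) -> list[tuple[TreeNode, TreeNode]]:
        """(parent, child) pairs; in unrooted terms, one per tree edge
        unless the root has degree 2 (then its two edges form one)."""
        out = []
        for node in self.preorder():
            for child in node.children:
                out.append((node, child))
        return out

    def is_binary_unrooted(self) -> bool:
        degs = []
        for node in self.preorder():
            deg = len(node.children) + (0 if node is self.root else 1)
            if not node.is_leaf:
                degs.append(deg)
        root_deg = len(self.root.children)
        if root_deg == 2:  # rooted binary representation of unrooted binary
            degs.remove(2)
        return all(d == 3 for d in degs)

    # -- bipartitions ------------------------------------------------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions of the unrooted tree.

        Each is represented canonically by the leaf set *not* containing
        the lexicographically smallest taxon.  A binary tree on n leaves
        has exactly n - 3 of them; unresolved (multifurcating) trees yield
        only the bipartitions of their resolved edges.
        """
        all_labels = frozenset(self.leaf_labels())
        anchor = min(all_labels)
        n = len(all_labels)
        out: set[frozenset[str]] = set()

        def below(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            acc: set[str] = set()
            for c in node.children:
                s = below(c)
                if 2 <= len(s) <= n - 2:
                    out.add(s if anchor not in s else all_labels - s)
                acc.update(s)
            return frozenset(acc)

        below(self.root)
        return out

    # -- distances ---------------------------------------------------------

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths (sum of branch lengths)."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}
            groups = []
            for c in node.children:
                g = {lab: d + c.length for lab, d in walk(c).items()}
                groups.append(g)
            for ga, gb in combinations(groups, 2):
                for la, da in ga.items():
                    for lb, db in gb.items():
                        key = (la, lb) if la < lb else (lb, la)
                        dists[key] = da + db
            merged = {}
            for g in groups:
                merged.update(g)
            return merged

        walk(self.root)
        return dists

    # -- Newick ------------------------------------------------------------

    def to_newick(self, precision: int = 10) -> str:
        def fmt(node: TreeNode, top: bool) -> str:
            if node.is_leaf:
                body = node.label or ""
            else:
                body = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
                if node.label:
                    body += node.label
            if top:
                return body
            return f"{body}:{node.length:.{precision}g}"

        return fmt(self.root, True) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(data=text, schema="newick")
        return cls(_from_dendropy(dtree.seed_node))

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(), schema="newick", taxon_namespace=taxon_namespace
        )


def _from_dendropy(dnode) -> TreeNode:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.is_leaf():
        label = dnode.label
    node = TreeNode(label=label, length=dnode.edge.length or 0.0)
    node.children = [_from_dendropy(c) for c in dnode.child_nodes()]
    return node
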
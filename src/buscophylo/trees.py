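"""Unrooted-tree utilities: bipartitions, restriction, NNI, pruning.

Trees are held as :class:`dendropy.Tree` objects and interpreted as
unrooted; the seed node is an arbitrary anchoring point.  A bipartition
(split) is the two-block partition of the leaf set induced by removing one
internal edge; it is the unit of all topological comparison downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import dendropy

__all__ = [
    "Bipartition",
    "bipartitions",
    "internal_edge_nodes",
    "leaf_labels",
    "nni",
    "prune_to_taxa",
    "read_newick",
    "read_newick_list",
    "write_newick",
]


@dataclass(frozen=True)
class Bipartition:
    """A nontrivial split of a taxon set into two blocks.

    Blocks are stored in a canonical order (smaller block first; ties broken
    lexicographically) so equality and hashing are well defined regardless
    of which side of the edge was enumerated first.
    """

    block_a: frozenset
    block_b: frozenset

    @staticmethod
    def make(one: Iterable[str], other: Iterable[str]) -> "Bipartition":
        a, b = frozenset(one), frozenset(other)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("both blocks of a bipartition need >= 2 taxa")
        if a & b:
            raise ValueError("bipartition blocks overlap")
        key_a = (len(a), min(a))
        key_b = (len(b), min(b))
        if key_b < key_a:
            a, b = b, a
        return Bipartition(a, b)

    @property
    def taxa(self) -> frozenset:
        return self.block_a | self.block_b

    def restrict(self, taxa: Iterable[str]) -> Optional["Bipartition"]:
        """Project onto a taxon subset; None if uninformative there.

        A split is uninformative on a subset when either block intersects it
        in fewer than two taxa (the restricted split is then trivial).
        """
        t = frozenset(taxa)
        a = self.block_a & t
        b = self.block_b & t
        if len(a) < 2 or len(b) < 2:
            return None
        return Bipartition.make(a, b)

    def conflicts_with(self, other: "Bipartition") -> bool:
        """True iff the two splits (on the same taxon set) are incompatible.

        Two splits A|B and X|Y on one taxon set are compatible iff at least
        one of the four pairwise intersections is empty.
        """
        if self.taxa != other.taxa:
            raise ValueError("conflict test requires a common taxon set")
        if self == other:
            return False
        return (
            bool(self.block_a & other.block_a)
            and bool(self.block_a & other.block_b)
            and bool(self.block_b & other.block_a)
            and bool(self.block_b & other.block_b)
        )


def leaf_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def bipartitions(tree: dendropy.Tree) -> set:
    """All nontrivial bipartitions of an unrooted tree, one per internal edge.

    A binary unrooted tree on n leaves yields n - 3 splits; trees with
    fewer than 4 leaves (or a star topology) yield the empty set.
    """
    all_taxa = leaf_labels(tree)
    if len(all_taxa) < 4:
        return set()
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        above = all_taxa - below
        if len(below) >= 2 and len(above) >= 2:
            out.add(Bipartition.make(below, above))
    return out


def internal_edge_nodes(tree: dendropy.Tree) -> list:
    """Child nodes of internal edges (each node identifies one split)."""
    nodes = []
    n_leaves = len(leaf_labels(tree))
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = sum(1 for _ in node.leaf_iter())
        if below >= 2 and n_leaves - below >= 2:
            nodes.append(node)
    return nodes


def nni(tree: dendropy.Tree, edge_child: dendropy.Node, swap_choice: int = 0) -> None:
    """Nearest-neighbor interchange around the internal edge above ``edge_child``.

    Swaps one child subtree of ``edge_child`` with one sibling subtree on the
    far side of the edge, in place.  ``swap_choice`` selects among the
    alternative exchanges (taken modulo the number available), so the two
    distinct NNI neighbours of a binary tree are reachable.
    """
    parent = edge_child.parent_node
    if parent is None or edge_child.is_leaf():
        raise ValueError("NNI needs an internal edge (internal non-seed node)")
    near = list(edge_child.child_nodes())
    far = [c for c in parent.child_nodes() if c is not edge_child]
    if not near or not far:
        raise ValueError("degenerate edge for NNI")
    a = near[swap_choice % len(near)]
    b = far[(swap_choice // len(near)) % len(far)]
    edge_child.remove_child(a)
    parent.remove_child(b)
    edge_child.add_child(b)
    parent.add_child(a)


def prune_to_taxa(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Return a copy of the tree restricted to ``keep`` leaves.

    Degree-two nodes created by leaf removal are suppressed with their
    incident branch lengths summed, so path lengths among retained taxa are
    preserved.
    """
    keep = set(keep)
    out = tree.clone(depth=1)
    drop = [lf.taxon for lf in out.leaf_node_iter() if lf.taxon.label not in keep]
    if drop:
        out.prune_taxa(drop, suppress_unifurcations=True)
    # prune_taxa can leave a unifurcating seed node; re-anchor if so
    seed = out.seed_node
    while len(seed.child_nodes()) == 1:
        child = seed.child_nodes()[0]
        seed.remove_child(child)
        out.seed_node = child
        child.parent_node = None
        child.edge.length = None
        seed = child
    return out


def read_newick(path_or_str, taxon_namespace=None) -> dendropy.Tree:
    kwargs = {"schema": "newick", "preserve_underscores": True}
    if taxon_namespace is not None:
        kwargs["taxon_namespace"] = taxon_namespace
    if isinstance(path_or_str, str) and path_or_str.lstrip().startswith("("):
        return dendropy.Tree.get(data=path_or_str, **kwargs)
    return dendropy.Tree.get(path=str(path_or_str), **kwargs)


def read_newick_list(path, taxon_namespace=None) -> list:
    kwargs = {"schema": "newick", "preserve_underscores": True}
    if taxon_namespace is not None:
        kwargs["taxon_namespace"] = taxon_namespace
    return list(dendropy.TreeList.get(path=str(path), **kwargs))


def write_newick(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s
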
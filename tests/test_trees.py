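"""Bipartition machinery checked against independent oracles.

The brute-force oracle enumerates unrooted binary trees as nested
tuples and derives splits by direct subtree/complement bookkeeping,
never touching the package's tree code; dendropy's own bipartition
encoding and Robinson-Foulds distance provide a second, library route.
"""

import dendropy
import pytest
from hypothesis import given
from hypothesis import strategies as st

from buscophylo.trees import (
    Bipartition,
    bipartitions,
    internal_edge_nodes,
    leaf_labels,
    nni,
    prune_to_taxa,
    read_newick,
)

# ---------------------------------------------------------------- oracle


def insert_leaf_everywhere(sub, leaf):
    yield (sub, leaf)
    if isinstance(sub, tuple):
        a, b = sub
        for na in insert_leaf_everywhere(a, leaf):
            yield (na, b)
        for nb in insert_leaf_everywhere(b, leaf):
            yield (a, nb)


def all_unrooted_trees(labels):
    """All unrooted binary topologies as (x, y, z) root triples."""
    assert len(labels) >= 3
    trees = [(labels[0], labels[1], labels[2])]
    for leaf in labels[3:]:
        nxt = []
        for x, y, z in trees:
            for nx in insert_leaf_everywhere(x, leaf):
                nxt.append((nx, y, z))
            for ny in insert_leaf_everywhere(y, leaf):
                nxt.append((x, ny, z))
            for nz in insert_leaf_everywhere(z, leaf):
                nxt.append((x, y, nz))
        trees = nxt
    return trees


def tuple_leaves(sub):
    if isinstance(sub, tuple):
        out = set()
        for child in sub:
            out |= tuple_leaves(child)
        return out
    return {sub}


def tuple_splits(tree):
    """Nontrivial splits of a root-triple tree, by direct enumeration."""
    universe = frozenset(tuple_leaves(tree[0]) | tuple_leaves(tree[1]) | tuple_leaves(tree[2]))
    splits = set()

    def visit(sub):
        below = frozenset(tuple_leaves(sub))
        if len(below) >= 2 and len(universe - below) >= 2:
            splits.add(frozenset({below, universe - below}))
        if isinstance(sub, tuple):
            for child in sub:
                visit(child)

    for top in tree:
        visit(top)
    return splits


def tuple_newick(sub):
    if isinstance(sub, tuple):
        return "(" + ",".join(tuple_newick(c) for c in sub) + ")"
    return sub


def as_split_set(bips):
    return {frozenset({b.block_a, b.block_b}) for b in bips}


# ----------------------------------------------------------------- tests


@pytest.mark.parametrize("n", [4, 5, 6])
def test_bipartitions_match_enumeration_oracle(n):
    labels = [f"T{i}" for i in range(n)]
    trees = all_unrooted_trees(labels)
    expected_counts = {4: 3, 5: 15, 6: 105}
    assert len(trees) == expected_counts[n]
    for tup in trees:
        tree = read_newick(tuple_newick(tup) + ";")
        mine = bipartitions(tree)
        assert len(mine) == n - 3
        assert as_split_set(mine) == tuple_splits(tup)


def test_star_tree_has_no_bipartitions():
    tree = read_newick("(A,B,C,D,E);")
    assert bipartitions(tree) == set()


def test_quartet_bipartition():
    tree = read_newick("((A,B),(C,D));")
    bips = bipartitions(tree)
    assert as_split_set(bips) == {
        frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
    }


def test_restrict_examples():
    bip = Bipartition.make({"A", "B"}, {"C", "D", "E"})
    assert bip.restrict({"A", "B", "C", "D"}) == Bipartition.make({"A", "B"}, {"C", "D"})
    assert bip.restrict({"A", "C", "D"}) is None
    assert bip.restrict(bip.taxa) == bip


def test_restriction_matches_pruned_tree_splits():
    """restrict() agrees with re-extracting splits from the pruned tree."""
    labels = [f"T{i}" for i in range(7)]
    for tup in all_unrooted_trees(labels)[::97]:
        tree = read_newick(tuple_newick(tup) + ";")
        keep = set(labels[:5])
        pruned = prune_to_taxa(tree, keep)
        restricted = {
            frozenset({b.block_a, b.block_b})
            for b in (bip.restrict(keep) for bip in bipartitions(tree))
            if b is not None
        }
        assert restricted == as_split_set(bipartitions(pruned))


def test_conflicts_with_requires_common_taxa_and_detects_incompatibility():
    b1 = Bipartition.make({"A", "B"}, {"C", "D"})
    b2 = Bipartition.make({"A", "C"}, {"B", "D"})
    assert b1.conflicts_with(b2)
    assert not b1.conflicts_with(b1)
    with pytest.raises(ValueError):
        b1.conflicts_with(Bipartition.make({"A", "B"}, {"C", "E"}))


def test_bipartition_canonical_equality():
    assert Bipartition.make({"A", "B"}, {"C", "D", "E"}) == Bipartition.make(
        {"C", "D", "E"}, {"A", "B"}
    )


@given(st.integers(0, 2**31 - 1))
def test_nni_changes_exactly_the_designated_split(seed):
    from buscophylo.synth import gen_species_tree
    import numpy as np

    rng = np.random.default_rng(seed)
    tree = gen_species_tree(8, int(rng.integers(1000)))
    before = bipartitions(tree)
    nodes = [n for n in internal_edge_nodes(tree) if n.parent_node is not None]
    node = nodes[int(rng.integers(len(nodes)))]
    below = frozenset(lf.taxon.label for lf in node.leaf_iter())
    target = Bipartition.make(below, leaf_labels(tree) - below)
    nni(tree, node)
    after = bipartitions(tree)
    assert target in before and target not in after
    assert len(before - after) == 1 and len(after - before) == 1
    (new,) = after - before
    assert target.conflicts_with(new)


def test_count_conflicts_matches_dendropy_rf():
    """Shared-split complement equals dendropy's RF distance halved."""
    from buscophylo.treesignal import count_conflicts
    from buscophylo.synth import gen_species_tree
    from dendropy.calculate import treecompare
    import numpy as np

    for seed in range(8):
        rng = np.random.default_rng(seed)
        t1 = gen_species_tree(9, seed)
        t2 = gen_species_tree(9, seed)
        for _ in range(int(rng.integers(0, 4))):
            nodes = [n for n in internal_edge_nodes(t2) if n.parent_node is not None]
            nni(t2, nodes[int(rng.integers(len(nodes)))], int(rng.integers(4)))
        n, edges = count_conflicts(t1, t2)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                               taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                               taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        assert 2 * n == treecompare.symmetric_difference(d1, d2)
        assert len(edges) == n
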
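"""Internode certainty, gene-signal scores and bootstrap machinery."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from buscophylo.synth import SynthConfig, gen_gene_trees, gen_species_tree
from buscophylo.trees import Bipartition, bipartitions, internal_edge_nodes, nni, read_newick
from buscophylo.treesignal import (
    SplitFrequencies,
    abs_score,
    annotate_ic,
    count_conflicts,
    internode_certainty,
    map_support,
    multilocus_bootstrap,
    rank_genes,
    rtc_score,
    split_frequencies,
    subset_overlap,
)

REF = Bipartition.make({"A", "B"}, {"C", "D"})
ALT = Bipartition.make({"A", "C"}, {"B", "D"})


def sf(f0, conflicts=(), n=100):
    return SplitFrequencies(
        reference=REF,
        reference_frequency=float(f0),
        conflicts=[(ALT, float(c)) for c in conflicts],
        n_informative=n,
    )


class TestInternodeCertainty:
    def test_no_conflict_is_certain(self):
        assert internode_certainty(sf(30)) == 1.0

    def test_equal_frequencies_are_uninformative(self):
        assert internode_certainty(sf(10, [10])) == pytest.approx(0.0)

    def test_worked_example_30_10(self):
        # 1 + 0.75 log2 0.75 + 0.25 log2 0.25
        assert internode_certainty(sf(30, [10])) == pytest.approx(0.18872, abs=1e-4)

    def test_sign_flips_when_reference_is_minority(self):
        assert internode_certainty(sf(10, [30])) == pytest.approx(-0.18872, abs=1e-4)

    def test_all_zero_is_undefined(self):
        assert math.isnan(internode_certainty(sf(0)))

    def test_ica_matches_ic_for_two_way(self):
        v_ic = internode_certainty(sf(30, [10]), mode="IC")
        v_ica = internode_certainty(sf(30, [10]), mode="ICA")
        assert v_ica == pytest.approx(v_ic)

    def test_ica_threshold_drops_rare_conflicts(self):
        # 4% conflict is below the 5% default retention threshold
        assert internode_certainty(sf(90, [4], n=100), mode="ICA") == 1.0

    def test_ica_three_way(self):
        # (60, 30, 10): 1 + sum p log3 p
        expect = 1 + sum(p * math.log(p, 3) for p in (0.6, 0.3, 0.1))
        assert internode_certainty(sf(60, [30, 10]), mode="ICA") == pytest.approx(expect)

    @given(st.integers(0, 500), st.integers(0, 500))
    def test_ic_bounded_and_signed(self, f0, f1):
        if f0 + f1 == 0:
            return
        v = internode_certainty(sf(f0, [f1] if f1 else []))
        assert -1.0 <= v <= 1.0
        if f1 == 0:
            assert v == 1.0
        elif f0 == f1:
            assert v == pytest.approx(0.0)
        elif f1 > f0:
            assert v <= 0

    @given(st.floats(0.5, 0.99))
    def test_two_way_closed_form_is_binary_entropy_complement(self, q):
        n = 10000
        f0, f1 = q * n, (1 - q) * n
        h2 = -(q * math.log2(q) + (1 - q) * math.log2(1 - q))
        assert internode_certainty(sf(f0, [f1])) == pytest.approx(1 - h2)


class TestSplitFrequencies:
    def test_concordant_trees_give_full_support(self, clean_dataset):
        ds = clean_dataset
        for bip in bipartitions(ds.species_tree):
            f = split_frequencies(bip, ds.gene_trees)
            assert f.reference_frequency == len(ds.gene_trees)
            assert f.conflicts == []

    def test_counts_match_truth_at_discordant_edge(self):
        species = gen_species_tree(12, 3)
        cfg = SynthConfig(
            n_taxa=12, n_genes=200, discordant_fraction=0.3,
            missing_taxon_rate=0.0, codon_length_range=(10, 20), seed=3,
        )
        trees, truth = gen_gene_trees(species, cfg)
        n_disc = sum(1 for v in truth.gene_topology.values() if v == "alternative")
        f = split_frequencies(truth.discordant_edge, trees)
        assert f.reference_frequency == 200 - n_disc
        assert f.conflicts[0][1] == n_disc
        # binomial 99% sanity band around 0.3 * 200
        assert abs(n_disc - 60) <= 3 * math.sqrt(200 * 0.3 * 0.7)

    def test_uninformative_trees_are_skipped(self):
        ref = Bipartition.make({"A", "B"}, {"C", "D", "E"})
        trees = [read_newick("((A,C),(D,E));")]  # B absent: block A too small
        f = split_frequencies(ref, trees)
        assert f.n_informative == 0

    def test_partial_tree_consistency(self):
        """Dropping taxa outside one split's support leaves its counts alone."""
        species = gen_species_tree(10, 7)
        cfg = SynthConfig(
            n_taxa=10, n_genes=60, discordant_fraction=0.4,
            missing_taxon_rate=0.0, codon_length_range=(10, 20), seed=7,
        )
        trees, truth = gen_gene_trees(species, cfg)
        ref = truth.discordant_edge
        full = split_frequencies(ref, trees)
        from buscophylo.trees import leaf_labels, prune_to_taxa

        # delete a taxon not involved in the reference split's small block
        # nor in the NNI exchange, so every restriction stays informative
        involved = set(ref.block_a)
        if full.conflicts:
            involved |= set(full.conflicts[0][0].block_a)
        victim = sorted(set(ref.block_b) - involved)[0]
        pruned = [prune_to_taxa(t, leaf_labels(t) - {victim}) for t in trees]
        part = split_frequencies(ref, pruned)
        assert part.n_informative == full.n_informative
        assert part.reference_frequency == full.reference_frequency
        assert [c for _, c in part.conflicts] == [c for _, c in full.conflicts]

    def test_trivial_reference_rejected(self):
        trivial = Bipartition(frozenset({"A"}), frozenset({"B", "C"}))
        with pytest.raises(ValueError):
            split_frequencies(trivial, [])


class TestAnnotateIC:
    def test_identical_gene_trees_give_unit_ic_everywhere(self):
        ref = gen_species_tree(10, 1)
        values, mean = annotate_ic(ref, [ref.clone(depth=1) for _ in range(20)])
        assert mean == 1.0
        assert all(v == 1.0 for v in values.values())

    def test_half_discordant_edge_has_zero_ic(self):
        species = gen_species_tree(10, 5)
        cfg = SynthConfig(
            n_taxa=10, n_genes=400, discordant_fraction=0.5,
            missing_taxon_rate=0.0, codon_length_range=(10, 20), seed=5,
        )
        trees, truth = gen_gene_trees(species, cfg)
        values, _ = annotate_ic(species, trees)
        # 1 - H2(q) with q near 0.5: |IC| stays near 0
        assert abs(values[truth.discordant_edge]) < 0.05
        others = [v for b, v in values.items() if b != truth.discordant_edge]
        assert all(v == 1.0 for v in others)


class TestGeneSignal:
    def test_abs_identical_replicates(self):
        ml = gen_species_tree(8, 2)
        boots = [ml.clone(depth=1) for _ in range(10)]
        assert abs_score(boots, ml) == 100.0
        assert rtc_score(boots, ml) == 1.0

    def test_abs_counting(self):
        ml = read_newick("((A,B),(C,D));")
        alt = read_newick("((A,C),(B,D));")
        boots = [ml.clone(depth=1)] * 40 + [alt.clone(depth=1)] * 60
        assert abs_score(boots, ml) == pytest.approx(40.0)

    def test_abs_zero_when_disjoint(self):
        ml = read_newick("((A,B),(C,D));")
        alt = read_newick("((A,C),(B,D));")
        assert abs_score([alt] * 5, ml) == 0.0

    def test_rtc_worked_example_75_25(self):
        ml = read_newick("((A,B),(C,D));")
        alt = read_newick("((A,C),(B,D));")
        boots = [ml] * 75 + [alt] * 25
        assert rtc_score(boots, ml) == pytest.approx(0.18872, abs=1e-4)

    def test_rtc_zero_on_even_split(self):
        ml = read_newick("((A,B),(C,D));")
        alt = read_newick("((A,C),(B,D));")
        assert rtc_score([ml] * 50 + [alt] * 50, ml) == pytest.approx(0.0)


class TestRanking:
    def test_study_subset_sizes(self):
        scores = {f"g{i:04d}": float(i) for i in range(1233)}
        assert len(rank_genes(scores, 0.5)) == 616
        assert len(rank_genes(scores, 0.25)) == 308

    def test_tie_break_is_lexicographic(self):
        assert rank_genes({"a": 1, "b": 1, "c": 0, "d": 0}, 0.5) == ["a", "b"]

    @given(st.integers(1, 300), st.floats(0.01, 1.0))
    def test_subset_size_law(self, n, frac):
        scores = {f"g{i}": float(i % 7) for i in range(n)}
        assert len(rank_genes(scores, frac)) == math.floor(frac * n)

    def test_rank_rejects_empty(self):
        with pytest.raises(ValueError):
            rank_genes({}, 0.5)

    def test_subset_overlap(self):
        assert subset_overlap({"a", "b"}, {"a", "b"}) == (1.0, 2)
        assert subset_overlap({"a"}, {"b"}) == (0.0, 0)
        j, shared = subset_overlap({"a", "b", "c", "d"}, {"c", "d", "e", "f"})
        assert j == pytest.approx(1 / 3) and shared == 2


class TestConflictsAndBootstrap:
    def test_identical_trees_have_no_conflicts(self):
        t = gen_species_tree(12, 9)
        assert count_conflicts(t, t.clone(depth=1)) == (0, [])

    def test_single_nni_gives_one_conflict(self):
        t1 = gen_species_tree(9, 4)
        t2 = t1.clone(depth=1)
        nodes = [n for n in internal_edge_nodes(t2) if n.parent_node is not None]
        nni(t2, nodes[0])
        n, edges = count_conflicts(t1, t2)
        assert n == 1 and len(edges) == 1

    def test_count_conflicts_rejects_leaf_mismatch(self):
        with pytest.raises(ValueError):
            count_conflicts(read_newick("((A,B),(C,D));"), read_newick("((A,B),(C,E));"))

    def test_multilocus_bootstrap_shapes_and_determinism(self):
        t = read_newick("((A,B),(C,D));")
        boot_sets = {f"g{i}": [t] * 5 for i in range(7)}
        reps1 = multilocus_bootstrap(boot_sets, 10, seed=42)
        reps2 = multilocus_bootstrap(boot_sets, 10, seed=42)
        assert len(reps1) == 10
        assert all(sorted(r) == sorted(boot_sets) for r in reps1)
        for r1, r2 in zip(reps1, reps2):
            assert {g: id(t) for g, t in r1.items()} == {g: id(t) for g, t in r2.items()}

    def test_multilocus_bootstrap_single_tree_sets(self):
        t = read_newick("((A,B),(C,D));")
        reps = multilocus_bootstrap({"g": [t]}, 5, seed=0)
        assert all(r["g"] is t for r in reps)
        with pytest.raises(ValueError):
            multilocus_bootstrap({"g": []}, 5, seed=0)

    def test_map_support_percentages(self):
        ml = read_newick("((A,B),(C,D));")
        alt = read_newick("((A,C),(B,D));")
        reps = [ml] * 95 + [alt] * 5
        (support,) = map_support(ml, reps).values()
        assert support == 95
        (zero,) = map_support(ml, [alt] * 10).values()
        assert zero == 0
        with pytest.raises(ValueError):
            map_support(ml, [read_newick("((A,B),(C,E));")])
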
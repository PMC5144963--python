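"""Bipartition-based phylogenetic signal and incongruence statistics.

Internode certainty (IC) quantifies, for one internal branch of a
reference tree, how decisively a collection of gene trees supports its
bipartition against the most prevalent conflicting bipartition.  With
support count f0 and top-conflict count f1, and p_i = f_i/(f0+f1),

    IC = 1 + p0*log2(p0) + p1*log2(p1),

negated when the conflict outnumbers the support; IC = 1 when no
conflict is observed and IC = 0 at a 50/50 split.  ICA generalises this
to the reference plus all retained conflicting bipartitions (k+1
frequencies, logarithm base k+1).  Gene trees may be partial (missing
taxa): a tree counts toward a reference bipartition only when that
bipartition restricted to the tree's taxa is still informative, and the
frequencies are the observed counts among those informative trees.

Also here: average bootstrap support (ABS) and relative tree certainty
(RTC) for ranking genes by signal, conflict counting between two trees
(shared-bipartition complement; RF distance / 2 for binary trees), the
multilocus bootstrap resampler, and bootstrap-support mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from .trees import Bipartition, bipartitions, internal_edge_nodes, leaf_labels

__all__ = [
    "SplitFrequencies",
    "split_frequencies",
    "internode_certainty",
    "annotate_ic",
    "abs_score",
    "rtc_score",
    "rank_genes",
    "subset_overlap",
    "count_conflicts",
    "multilocus_bootstrap",
    "map_support",
]

ICA_DEFAULT_THRESHOLD = 0.05


@dataclass
class SplitFrequencies:
    """Observed support/conflict counts for one reference bipartition."""

    reference: Bipartition
    reference_frequency: float
    conflicts: List[Tuple[Bipartition, float]] = field(default_factory=list)  # descending
    n_informative: int = 0


def _tree_profiles(gene_trees: Iterable[dendropy.Tree]):
    """Precompute (taxon set, bipartition set) per gene tree."""
    return [(leaf_labels(t), bipartitions(t)) for t in gene_trees]


def split_frequencies(
    ref_bip: Bipartition,
    gene_trees: Sequence[dendropy.Tree] | None = None,
    profiles=None,
) -> SplitFrequencies:
    """Tally support for and conflict with one reference bipartition.

    A gene tree is informative iff the reference restricted to its taxon
    set is nontrivial.  Among informative trees, trees containing the
    restricted reference count as support; in the remaining trees every
    bipartition incompatible with the restricted reference is tallied,
    pooled into restriction-compatibility classes (splits from different
    taxon subsets join one class when they agree on their shared taxa).
    Frequencies are raw counts over informative trees.
    """
    if len(ref_bip.block_a) < 2 or len(ref_bip.block_b) < 2:
        raise ValueError("reference bipartition is trivial")
    if profiles is None:
        profiles = _tree_profiles(gene_trees or [])
    support = 0
    informative = 0
    # conflict classes pooled by restriction-compatibility: two conflicting
    # splits observed on different taxon subsets belong to one class when
    # they agree (and are nontrivial) on their shared taxa, so a conflict
    # fragmented across partial trees still accumulates into one frequency
    classes: List[List] = []  # [representative Bipartition, count]
    for taxa, bips in profiles:
        r = ref_bip.restrict(taxa)
        if r is None:
            continue
        informative += 1
        if r in bips:
            support += 1
            continue
        for b in bips:
            if not r.conflicts_with(b):
                continue
            for cls in classes:
                rep = cls[0]
                shared = rep.taxa & b.taxa
                pb, pr = b.restrict(shared), rep.restrict(shared)
                if pb is not None and pb == pr:
                    cls[1] += 1
                    if len(b.taxa) > len(rep.taxa):
                        cls[0] = b
                    break
            else:
                classes.append([b, 1])
    conflicts = sorted(
        classes, key=lambda kv: (-kv[1], sorted(kv[0].block_a), sorted(kv[0].block_b))
    )
    return SplitFrequencies(
        reference=ref_bip,
        reference_frequency=float(support),
        conflicts=[(b, float(c)) for b, c in conflicts],
        n_informative=informative,
    )


def _plogb(p: float, base: float) -> float:
    return p * math.log(p, base) if p > 0 else 0.0


def internode_certainty(
    f: SplitFrequencies,
    mode: str = "IC",
    ica_threshold: float = ICA_DEFAULT_THRESHOLD,
) -> float:
    """Entropy-based certainty in [-1, 1] for one internode.

    ``IC`` uses the reference and single most prevalent conflict; ``ICA``
    uses the reference plus every conflict with frequency at least
    ``ica_threshold`` x informative-tree count (an unbounded tail of
    near-zero splits would otherwise make ICA degenerate).  The value is
    negated when the reference is not the most frequent bipartition
    considered.  No observed conflict gives 1; all-zero frequencies give
    NaN (undefined).
    """
    f0 = f.reference_frequency
    if mode == "IC":
        if not f.conflicts:
            return float("nan") if f0 == 0 else 1.0
        f1 = f.conflicts[0][1]
        tot = f0 + f1
        if tot == 0:
            return float("nan")
        val = 1.0 + _plogb(f0 / tot, 2) + _plogb(f1 / tot, 2)
        return -val if f1 > f0 else val
    if mode == "ICA":
        cutoff = ica_threshold * f.n_informative
        kept = [c for _, c in f.conflicts if c >= cutoff]
        if not kept:
            return float("nan") if f0 == 0 else 1.0
        freqs = [f0] + kept
        tot = sum(freqs)
        if tot == 0:
            return float("nan")
        base = len(freqs)
        val = 1.0 + sum(_plogb(x / tot, base) for x in freqs)
        return -val if max(kept) > f0 else val
    raise ValueError(f"unknown mode {mode!r}")


def annotate_ic(
    ref_tree: dendropy.Tree,
    gene_trees: Sequence[dendropy.Tree],
    mode: str = "IC",
    ica_threshold: float = ICA_DEFAULT_THRESHOLD,
) -> Tuple[Dict[Bipartition, float], float]:
    """IC for every internal branch of a reference tree, plus the mean.

    Returns a mapping from each internode's bipartition to its certainty
    and the mean over all internodes (to three decimals).  NaN internodes
    (no informative gene tree) are excluded from the mean.
    """
    profiles = _tree_profiles(gene_trees)
    values: Dict[Bipartition, float] = {}
    for bip in sorted(bipartitions(ref_tree), key=lambda b: (sorted(b.block_a), sorted(b.block_b))):
        sf = split_frequencies(bip, profiles=profiles)
        values[bip] = internode_certainty(sf, mode=mode, ica_threshold=ica_threshold)
    finite = [v for v in values.values() if not math.isnan(v)]
    mean = round(sum(finite) / len(finite), 3) if finite else float("nan")
    return values, mean


def abs_score(
    boot_trees: Sequence[dendropy.Tree], ml_tree: dendropy.Tree
) -> float:
    """Average bootstrap support across the internal edges of one gene tree.

    Per edge: the percentage of bootstrap replicates whose (restricted)
    bipartition set contains that edge's split; ABS is the mean percentage.
    """
    if not boot_trees:
        raise ValueError("boot_trees is empty")
    ml_bips = bipartitions(ml_tree)
    if not ml_bips:
        return float("nan")
    profiles = _tree_profiles(boot_trees)
    supports = []
    for bip in ml_bips:
        n = 0
        for taxa, bips in profiles:
            r = bip.restrict(taxa)
            if r is not None and r in bips:
                n += 1
        supports.append(100.0 * n / len(boot_trees))
    return float(sum(supports) / len(supports))


def rtc_score(
    boot_trees: Sequence[dendropy.Tree],
    ml_tree: dendropy.Tree,
    ica_threshold: float = ICA_DEFAULT_THRESHOLD,
) -> float:
    """Relative tree certainty: mean IC over the gene tree's internodes,
    with bipartition frequencies drawn from its bootstrap replicates."""
    if not boot_trees:
        raise ValueError("boot_trees is empty")
    ml_bips = bipartitions(ml_tree)
    if not ml_bips:
        return float("nan")
    profiles = _tree_profiles(boot_trees)
    vals = []
    for bip in ml_bips:
        sf = split_frequencies(bip, profiles=profiles)
        vals.append(internode_certainty(sf, mode="IC", ica_threshold=ica_threshold))
    finite = [v for v in vals if not math.isnan(v)]
    return float(sum(finite) / len(finite)) if finite else float("nan")


def rank_genes(scores: Mapping[str, float], top_frac: float) -> List[str]:
    """Top fraction of genes by score, descending; floor(top_frac * n) genes.

    Ties are broken by gene name ascending, so ranking is deterministic.
    """
    if not scores:
        raise ValueError("empty score mapping")
    if not (0 < top_frac <= 1):
        raise ValueError("top_frac must be in (0, 1]")
    ordered = sorted(scores, key=lambda g: (-scores[g], g))
    return ordered[: math.floor(top_frac * len(scores))]


def subset_overlap(a: Iterable[str], b: Iterable[str]) -> Tuple[float, int]:
    """Jaccard index and shared count of two gene sets."""
    a, b = set(a), set(b)
    union = a | b
    inter = a & b
    if not union:
        return float("nan"), 0
    return len(inter) / len(union), len(inter)


def count_conflicts(
    tree_a: dendropy.Tree, tree_b: dendropy.Tree
) -> Tuple[int, List[Bipartition]]:
    """Internodes of tree_a whose bipartitions are absent from tree_b.

    For binary trees on the same leaf set this is symmetric and equals
    half the Robinson-Foulds distance.
    """
    if leaf_labels(tree_a) != leaf_labels(tree_b):
        raise ValueError("trees have different leaf sets")
    bips_a = bipartitions(tree_a)
    bips_b = bipartitions(tree_b)
    missing = sorted(bips_a - bips_b, key=lambda b: (sorted(b.block_a), sorted(b.block_b)))
    return len(missing), missing


def multilocus_bootstrap(
    boot_sets: Mapping[str, Sequence[dendropy.Tree]],
    n_reps: int,
    seed: int,
) -> List[Dict[str, dendropy.Tree]]:
    """Resample one bootstrap tree per gene per replicate.

    Draws are uniform with replacement, independent across genes and
    replicates, and deterministic under a fixed seed.
    """
    for gene, trees in boot_sets.items():
        if len(trees) == 0:
            raise ValueError(f"gene {gene!r} has an empty bootstrap set")
    rng = np.random.default_rng(seed)
    genes = sorted(boot_sets)
    reps = []
    for _ in range(n_reps):
        reps.append({g: boot_sets[g][int(rng.integers(len(boot_sets[g])))] for g in genes})
    return reps


def map_support(
    ref_tree: dendropy.Tree, replicate_trees: Sequence[dendropy.Tree]
) -> Dict[Bipartition, int]:
    """Bootstrap support (integer percent) per internal edge of ref_tree."""
    ref_taxa = leaf_labels(ref_tree)
    for t in replicate_trees:
        if leaf_labels(t) != ref_taxa:
            raise ValueError("replicate tree leaf set differs from reference")
    rep_bips = [bipartitions(t) for t in replicate_trees]
    out = {}
    for bip in bipartitions(ref_tree):
        n = sum(1 for bips in rep_bips if bip in bips)
        out[bip] = round(100.0 * n / len(replicate_trees)) if replicate_trees else 0
    return out
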
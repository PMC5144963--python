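"""Synthetic phylogenomic data with known ground truth.

Generates the full complement of inputs the pipeline consumes — a
species tree, discordant (possibly partial) gene trees, in-frame codon
alignments with CUG-Ser taxa and injected long-branch rogue sequences,
bootstrap tree sets of controllable sharpness, and BUSCO-style candidate
hit tables — together with a truth record of every injected pathology,
so each downstream stage can be validated by parameter recovery.

Modelling choices, deliberately minimal:

* sequences evolve by i.i.d. per-nucleotide Jukes-Cantor substitution
  within codons; codons that become stops are resampled, so every
  emitted sequence is stop-free under both genetic codes;
* topological discordance is a single nearest-neighbor interchange at
  one designated internal edge shared by all discordant genes, which
  gives exact control over which internode conflicts and by how much;
* a rogue sequence is made by scaling one terminal branch by
  ``rogue_branch_factor`` before simulating, and the scaled length is
  written into the emitted gene tree, so the long-branch filter is
  testable from trees alone;
* terminal branch lengths are narrowly dispersed (lognormal,
  sigma = 0.25) so the rogue scale factor, not background rate
  variation, dominates the terminal-length distribution.

Identical (config, seed) reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from .busco import GeneRefStats, HitRecord
from .codons import CodonAlignment
from .trees import (
    Bipartition,
    bipartitions,
    internal_edge_nodes,
    leaf_labels,
    nni,
    prune_to_taxa,
    write_newick,
)

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "SynthDataset",
    "taxon_names",
    "gen_species_tree",
    "gen_gene_trees",
    "gen_codon_alignments",
    "gen_busco_hits",
    "gen_bootstrap_sets",
    "default_ref_stats",
    "generate",
    "write_dataset",
]

_NT = "ACGT"
# stop codons TAA/TAG/TGA as (A=0, C=1, G=2, T=3) index triples
_CTG = np.array([1, 3, 2], dtype=np.int8)

DEFAULT_STATUS_PROBS = {
    "complete": 0.90,
    "duplicated": 0.03,
    "fragmented": 0.04,
    "missing": 0.03,
}


@dataclass(frozen=True)
class SynthConfig:
    """Study-shaped generation parameters.

    Defaults emulate the target study's inputs: a 96-taxon universe,
    1233 gene families, ~90% taxon occupancy, a few percent of gene
    families carrying one spurious long-branch sequence, and trimmed
    codon alignments of 501-14,562 bp (167-4854 codons).
    """

    n_taxa: int = 96
    n_genes: int = 1233
    discordant_fraction: float = 0.3
    missing_taxon_rate: float = 0.1
    rogue_rate: float = 0.03
    rogue_branch_factor: float = 40.0
    codon_length_range: Tuple[int, int] = (167, 4854)
    cug_ser_taxa: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self):
        for name in ("discordant_fraction", "missing_taxon_rate", "rogue_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.codon_length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid codon_length_range {self.codon_length_range}")
        if self.rogue_branch_factor <= 0:
            raise ValueError("rogue_branch_factor must be positive")
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        object.__setattr__(self, "cug_ser_taxa", frozenset(self.cug_ser_taxa))


@dataclass
class SynthTruth:
    """What was injected, for parameter-recovery tests."""

    species_tree: Optional[dendropy.Tree] = None
    discordant_edge: Optional[Bipartition] = None
    gene_topology: Dict[str, str] = field(default_factory=dict)  # concordant | alternative
    rogue_taxa: Dict[str, Set[str]] = field(default_factory=dict)
    gene_status: Dict[Tuple[str, str], str] = field(default_factory=dict)

    def merge(self, other: "SynthTruth") -> "SynthTruth":
        return SynthTruth(
            species_tree=self.species_tree or other.species_tree,
            discordant_edge=self.discordant_edge or other.discordant_edge,
            gene_topology={**self.gene_topology, **other.gene_topology},
            rogue_taxa={**self.rogue_taxa, **other.rogue_taxa},
            gene_status={**self.gene_status, **other.gene_status},
        )


@dataclass
class SynthDataset:
    config: SynthConfig
    species_tree: dendropy.Tree
    gene_trees: List[dendropy.Tree]
    alignments: List[CodonAlignment]
    hits: List[HitRecord]
    ref_stats: Dict[str, GeneRefStats]
    truth: SynthTruth


def taxon_names(n: int) -> List[str]:
    return [f"t{i:03d}" for i in range(1, n + 1)]


def gene_names(n: int) -> List[str]:
    return [f"g{i:04d}" for i in range(1, n + 1)]


def _terminal_length(rng) -> float:
    return float(0.12 * np.exp(rng.normal(0.0, 0.25)))


def _internal_length(rng) -> float:
    return float(0.05 * np.exp(rng.normal(0.0, 0.5)))


def gen_species_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Random unrooted fully resolved tree with strictly positive lengths.

    Built by uniform random joins; the seed node is left trifurcating so
    the tree reads as unrooted (n - 3 internal branches).
    """
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace(taxon_names(n_taxa))
    nodes = []
    for taxon in tns:
        node = dendropy.Node(taxon=taxon)
        node.edge.length = _terminal_length(rng)
        nodes.append(node)
    while len(nodes) > 3:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = _internal_length(rng)
        nodes.append(parent)
    root = dendropy.Node()
    for node in nodes:
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def _find_edge_node(tree: dendropy.Tree, split: Bipartition):
    """Locate the internal node whose below-edge split equals ``split``."""
    all_taxa = leaf_labels(tree)
    for node in internal_edge_nodes(tree):
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if Bipartition.make(below, all_taxa - below) == split:
            return node
    return None


def gen_gene_trees(
    species_tree: dendropy.Tree, cfg: SynthConfig
) -> Tuple[List[dendropy.Tree], SynthTruth]:
    """Gene trees from the species tree with controlled discordance.

    A ``discordant_fraction`` share of genes receive one NNI around a
    single designated internal edge (the same edge and exchange for every
    discordant gene, so the conflicting bipartition is shared); each tree
    then independently drops taxa at ``missing_taxon_rate``, redrawing the
    drop set if fewer than 4 leaves would remain.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    taxa = sorted(leaf_labels(species_tree))
    candidates = internal_edge_nodes(species_tree)
    # designated edge must have a parent with a sibling subtree for the NNI
    candidates = [n for n in candidates if n.parent_node is not None]
    all_taxa = frozenset(taxa)
    edge_node = candidates[int(rng.integers(len(candidates)))]
    below = frozenset(lf.taxon.label for lf in edge_node.leaf_iter())
    designated = Bipartition.make(below, all_taxa - below)

    truth = SynthTruth(species_tree=species_tree, discordant_edge=designated)
    trees: List[dendropy.Tree] = []
    for gene in gene_names(cfg.n_genes):
        discordant = bool(rng.random() < cfg.discordant_fraction)
        tree = species_tree.clone(depth=1)
        tree.label = gene
        if discordant:
            node = _find_edge_node(tree, designated)
            nni(tree, node, swap_choice=0)
        if cfg.missing_taxon_rate > 0:
            while True:
                keep = [t for t in taxa if rng.random() >= cfg.missing_taxon_rate]
                if len(keep) >= 4:
                    break
            if len(keep) < len(taxa):
                pruned = prune_to_taxa(tree, keep)
                pruned.label = gene
                tree = pruned
        trees.append(tree)
        truth.gene_topology[gene] = "alternative" if discordant else "concordant"
    return trees, truth


def _is_stop(codons: np.ndarray) -> np.ndarray:
    t = codons[:, 0] == 3
    taa_tag = (codons[:, 1] == 0) & ((codons[:, 2] == 0) | (codons[:, 2] == 2))
    tga = (codons[:, 1] == 2) & (codons[:, 2] == 0)
    return t & (taa_tag | tga)


def _resample_stops(codons: np.ndarray, rng) -> np.ndarray:
    while True:
        idx = np.nonzero(_is_stop(codons))[0]
        if idx.size == 0:
            return codons
        codons[idx] = rng.integers(0, 4, size=(idx.size, 3), dtype=np.int8)


def _evolve(parent: np.ndarray, brlen: float, rng) -> np.ndarray:
    """Jukes-Cantor substitution over one branch, stop codons resampled."""
    child = parent.copy()
    flat = child.reshape(-1)
    p = 0.75 * (1.0 - np.exp(-4.0 * brlen / 3.0))
    mask = rng.random(flat.size) < p
    n = int(mask.sum())
    if n:
        flat[mask] = (flat[mask] + rng.integers(1, 4, size=n, dtype=np.int8)) % 4
    return _resample_stops(child, rng)


def _to_seq(codons: np.ndarray) -> str:
    return "".join(_NT[i] for i in codons.reshape(-1))


def gen_codon_alignments(
    gene_trees: Sequence[dendropy.Tree], cfg: SynthConfig
) -> Tuple[List[CodonAlignment], SynthTruth]:
    """Gapless in-frame codon alignments simulated on the gene trees.

    A ``rogue_rate`` share of genes get one rogue sequence: a randomly
    chosen leaf's terminal branch is multiplied by
    ``rogue_branch_factor`` *in the gene tree itself* (the scaled length
    is what downstream filters see) before the sequence is simulated.
    CUG-Ser taxa are flagged with the cug_ser code and guaranteed at
    least one CTG codon.  No sequence carries an in-frame stop.
    """
    gene_trees = list(gene_trees)
    if not gene_trees:
        raise ValueError("gene_trees is empty")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    lo, hi = cfg.codon_length_range
    truth = SynthTruth()
    alignments: List[CodonAlignment] = []
    for tree in gene_trees:
        gene = tree.label or "gene"
        n_codons = int(rng.integers(lo, hi + 1))
        rogue: Set[str] = set()
        if rng.random() < cfg.rogue_rate:
            leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
            pick = leaves[int(rng.integers(len(leaves)))]
            pick.edge.length = pick.edge.length * cfg.rogue_branch_factor
            rogue = {pick.taxon.label}
        truth.rogue_taxa[gene] = rogue

        root_seq = _resample_stops(
            rng.integers(0, 4, size=(n_codons, 3), dtype=np.int8), rng
        )
        seqs: Dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent = seqs[id(node.parent_node)]
            seqs[id(node)] = _evolve(parent, node.edge.length or 0.0, rng)

        rows: Dict[str, str] = {}
        codes: Dict[str, str] = {}
        for lf in sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label):
            label = lf.taxon.label
            arr = seqs[id(lf)]
            if label in cfg.cug_ser_taxa:
                codes[label] = "cug_ser"
                if not np.any(np.all(arr == _CTG, axis=1)):
                    arr[int(rng.integers(n_codons))] = _CTG
            else:
                codes[label] = "standard"
            rows[label] = _to_seq(arr)
        alignments.append(CodonAlignment(gene=gene, rows=rows, codes=codes))
    return alignments, truth


def default_ref_stats(genes: Iterable[str], seed: int) -> Dict[str, GeneRefStats]:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    out = {}
    for gene in genes:
        out[gene] = GeneRefStats(
            busco_gene=gene,
            bitscore_cutoff=float(np.round(rng.uniform(80, 200), 1)),
            ref_aligned_length=int(rng.integers(150, 601)),
        )
    return out


def gen_busco_hits(
    cfg: SynthConfig,
    ref_stats: Dict[str, GeneRefStats],
    status_probs: Optional[Dict[str, float]] = None,
) -> Tuple[List[HitRecord], SynthTruth]:
    """Candidate-hit tables with known classification labels.

    For each genome x gene a target label is drawn (defaults: 90%
    complete, 3% duplicated, 4% fragmented, 3% missing) and hits are
    constructed to realise it: complete = one above-cutoff full-length
    hit; duplicated = two; fragmented = above-cutoff hits at half the
    reference length; missing = no hits or a single below-cutoff hit.
    """
    probs = dict(status_probs or DEFAULT_STATUS_PROBS)
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError("status probabilities must sum to 1")
    labels = sorted(probs)
    pvec = np.array([probs[s] for s in labels])
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    truth = SynthTruth()
    hits: List[HitRecord] = []
    for genome in taxon_names(cfg.n_taxa):
        for gene in sorted(ref_stats):
            ref = ref_stats[gene]
            label = labels[int(rng.choice(len(labels), p=pvec))]
            truth.gene_status[(genome, gene)] = label
            if label == "complete":
                hits.append(
                    HitRecord(genome, gene, f"{genome}.{gene}.c1",
                              ref.bitscore_cutoff * 1.25, ref.ref_aligned_length)
                )
            elif label == "duplicated":
                for k in (1, 2):
                    hits.append(
                        HitRecord(genome, gene, f"{genome}.{gene}.c{k}",
                                  ref.bitscore_cutoff * (1.1 + 0.1 * k),
                                  ref.ref_aligned_length)
                    )
            elif label == "fragmented":
                hits.append(
                    HitRecord(genome, gene, f"{genome}.{gene}.c1",
                              ref.bitscore_cutoff * 1.2,
                              int(0.5 * ref.ref_aligned_length))
                )
            else:  # missing: either no candidate at all or one below cutoff
                if rng.random() < 0.5:
                    hits.append(
                        HitRecord(genome, gene, f"{genome}.{gene}.c1",
                                  ref.bitscore_cutoff * 0.5, ref.ref_aligned_length)
                    )
    return hits, truth


def gen_bootstrap_sets(
    gene_trees: Sequence[dendropy.Tree],
    n_boot: int,
    seed: int,
    sharpness: Optional[Dict[str, float]] = None,
    max_boot_nnis: int = 4,
) -> Dict[str, List[dendropy.Tree]]:
    """Perturbed-tree bootstrap sets of controllable sharpness.

    Each replicate is the gene tree with Binomial(max_boot_nnis,
    1 - sharpness) random NNIs applied; sharpness 1 gives replicates
    identical to the gene tree (ABS 100), sharpness 0 gives heavily
    shuffled replicates.  This stands in for ML rapid bootstrapping,
    whose alignment-level machinery is out of scope here.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    out: Dict[str, List[dendropy.Tree]] = {}
    for tree in gene_trees:
        gene = tree.label or "gene"
        q = (sharpness or {}).get(gene, 1.0)
        reps = []
        for _ in range(n_boot):
            rep = tree.clone(depth=1)
            n_moves = int(rng.binomial(max_boot_nnis, max(0.0, 1.0 - q)))
            for _ in range(n_moves):
                nodes = [n for n in internal_edge_nodes(rep) if n.parent_node is not None]
                if not nodes:
                    break
                node = nodes[int(rng.integers(len(nodes)))]
                nni(rep, node, swap_choice=int(rng.integers(4)))
            reps.append(rep)
        out[gene] = reps
    return out


def gene_length_profile(
    n_genes: int, total: int, lo: int, hi: int, rng
) -> List[int]:
    """Per-gene lengths in [lo, hi] summing exactly to ``total``.

    Draws uniform lengths, rescales to the target total, then spreads the
    rounding remainder one unit at a time over genes with slack.  Used to
    build matrices of a prescribed overall size from a realistic length
    distribution.
    """
    if not (n_genes * lo <= total <= n_genes * hi):
        raise ValueError("total not reachable within [lo, hi] per gene")
    draw = rng.integers(lo, hi + 1, size=n_genes).astype(float)
    lengths = np.clip(np.floor(draw * (total / draw.sum())).astype(int), lo, hi)
    diff = int(total - lengths.sum())
    i = 0
    while diff != 0:
        idx = i % n_genes
        if diff > 0 and lengths[idx] < hi:
            lengths[idx] += 1
            diff -= 1
        elif diff < 0 and lengths[idx] > lo:
            lengths[idx] -= 1
            diff += 1
        i += 1
    return [int(x) for x in lengths]


def random_codon_alignment(
    gene: str, taxa: Sequence[str], n_codons: int, rng
) -> CodonAlignment:
    """Gapless stop-free random codon alignment (no tree; shape fixtures).

    Used where only matrix geometry matters (concatenation, C12 site
    counts), not evolutionary signal.
    """
    lookup = np.frombuffer(b"ACGT", dtype="S1")
    rows = {}
    for taxon in taxa:
        arr = _resample_stops(
            rng.integers(0, 4, size=(n_codons, 3), dtype=np.int8), rng
        )
        rows[taxon] = lookup[arr.reshape(-1)].tobytes().decode()
    return CodonAlignment(gene=gene, rows=rows)


def gen_signal_dataset(
    n_taxa: int,
    n_genes: int,
    n_boot: int,
    seed: int,
    quality_range: Tuple[float, float] = (0.3, 1.0),
    max_gene_nnis: int = 4,
) -> Tuple[dendropy.Tree, List[dendropy.Tree], Dict[str, List[dendropy.Tree]], Dict[str, float]]:
    """Gene trees with heterogeneous per-gene phylogenetic signal.

    Each gene draws a quality q in ``quality_range``; its ML tree is the
    species tree with Binomial(max_gene_nnis, 1 - q) random NNIs, and its
    bootstrap replicates are perturbed at sharpness q.  Low-quality genes
    thus have both noisier bootstrap sets (low ABS/RTC) and more
    discordant topologies, the coupling that makes signal-based gene
    subsetting reduce incongruence.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    species = gen_species_tree(n_taxa, seed)
    quality: Dict[str, float] = {}
    ml_trees: List[dendropy.Tree] = []
    for gene in gene_names(n_genes):
        q = float(rng.uniform(*quality_range))
        quality[gene] = q
        tree = species.clone(depth=1)
        tree.label = gene
        n_moves = int(rng.binomial(max_gene_nnis, 1.0 - q))
        for _ in range(n_moves):
            nodes = [n for n in internal_edge_nodes(tree) if n.parent_node is not None]
            node = nodes[int(rng.integers(len(nodes)))]
            nni(tree, node, swap_choice=int(rng.integers(4)))
        ml_trees.append(tree)
    boot_sets = gen_bootstrap_sets(ml_trees, n_boot, seed, sharpness=quality)
    return species, ml_trees, boot_sets, quality


def generate(cfg: SynthConfig) -> SynthDataset:
    """Run every generator under one config and merge the truth records."""
    species = gen_species_tree(cfg.n_taxa, cfg.seed)
    trees, t1 = gen_gene_trees(species, cfg)
    alns, t2 = gen_codon_alignments(trees, cfg)
    refs = default_ref_stats(gene_names(cfg.n_genes), cfg.seed)
    hits, t3 = gen_busco_hits(cfg, refs)
    return SynthDataset(
        config=cfg,
        species_tree=species,
        gene_trees=trees,
        alignments=alns,
        hits=hits,
        ref_stats=refs,
        truth=t1.merge(t2).merge(t3),
    )


def write_dataset(ds: SynthDataset, outdir) -> None:
    """Write FASTA/newick/TSV/JSON artefacts; byte-stable under a fixed seed."""
    out = Path(outdir)
    (out / "genes").mkdir(parents=True, exist_ok=True)
    (out / "trees").mkdir(parents=True, exist_ok=True)
    write_newick(ds.species_tree, out / "species_tree.nwk")
    for tree in ds.gene_trees:
        write_newick(tree, out / "trees" / f"{tree.label}.nwk")
    for aln in ds.alignments:
        with open(out / "genes" / f"{aln.gene}.fasta", "w") as fh:
            for taxon in aln.rows:
                fh.write(f">{taxon}\n{aln.rows[taxon]}\n")
    with open(out / "hits.tsv", "w") as fh:
        fh.write("genome\tbusco_gene\tcandidate_id\tbit_score\taligned_length\n")
        for h in ds.hits:
            fh.write(
                f"{h.genome}\t{h.busco_gene}\t{h.candidate_id}"
                f"\t{h.bit_score:.1f}\t{h.aligned_length}\n"
            )
    with open(out / "ref_stats.tsv", "w") as fh:
        fh.write("busco_gene\tbitscore_cutoff\tref_aligned_length\n")
        for gene in sorted(ds.ref_stats):
            r = ds.ref_stats[gene]
            fh.write(f"{gene}\t{r.bitscore_cutoff:.1f}\t{r.ref_aligned_length}\n")
    with open(out / "taxa.txt", "w") as fh:
        fh.write("\n".join(taxon_names(ds.config.n_taxa)) + "\n")
    with open(out / "cug_ser_taxa.txt", "w") as fh:
        for t in sorted(ds.config.cug_ser_taxa):
            fh.write(t + "\n")
    truth = {
        "discordant_edge": (
            [sorted(ds.truth.discordant_edge.block_a),
             sorted(ds.truth.discordant_edge.block_b)]
            if ds.truth.discordant_edge else None
        ),
        "gene_topology": dict(sorted(ds.truth.gene_topology.items())),
        "rogue_taxa": {g: sorted(s) for g, s in sorted(ds.truth.rogue_taxa.items())},
        "gene_status": {
            f"{genome}|{gene}": status
            for (genome, gene), status in sorted(ds.truth.gene_status.items())
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
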
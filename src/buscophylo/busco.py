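"""BUSCO-style genome-completeness classification.

Each genome x gene combination is classified from its candidate hits as
complete, duplicated, fragmented or missing:

* hits are retained only if their alignment bit-score is strictly above
  the gene's preset cutoff (90% of the lowest reference bit-score);
* no retained hit -> missing;
* all retained hits shorter than 95% of the reference aligned length ->
  fragmented;
* otherwise one full-length retained hit -> complete, two or more ->
  duplicated.

Per-genome summaries report the fraction of genes in each category plus
the "phylo" count: complete single-copy genes that are additionally free
of in-frame stop codons and hence usable for matrix construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional

import pandas as pd

__all__ = [
    "HitRecord",
    "GeneRefStats",
    "GeneStatus",
    "classify_gene",
    "classify_table",
    "summarize_genome",
    "read_hit_table",
    "read_ref_stats",
    "write_summary",
]

STATUSES = ("complete", "duplicated", "fragmented", "missing")
FULL_LENGTH_FRAC = 0.95


@dataclass(frozen=True)
class HitRecord:
    genome: str
    busco_gene: str
    candidate_id: str
    bit_score: float
    aligned_length: int

    def __post_init__(self):
        if self.bit_score < 0 or self.aligned_length < 0:
            raise ValueError("bit_score and aligned_length must be nonnegative")


@dataclass(frozen=True)
class GeneRefStats:
    busco_gene: str
    bitscore_cutoff: float
    ref_aligned_length: int

    def __post_init__(self):
        if self.bitscore_cutoff < 0 or self.ref_aligned_length < 1:
            raise ValueError("invalid reference stats")


@dataclass(frozen=True)
class GeneStatus:
    genome: str
    busco_gene: str
    status: str


def classify_gene(
    hits: Iterable[HitRecord], ref: GeneRefStats, genome: Optional[str] = None
) -> GeneStatus:
    """Classify one genome x gene from its candidate hits.

    Bit-score comparison is strict (> cutoff); the 95%-of-reference length
    comparison is strict as well, so a hit at exactly 95% counts as
    full-length.
    """
    hits = list(hits)
    genomes = {h.genome for h in hits}
    genes = {h.busco_gene for h in hits}
    if len(genomes) > 1 or len(genes) > 1:
        raise ValueError("hits mix genomes or genes")
    if genes and genes != {ref.busco_gene}:
        raise ValueError(f"hits are for {genes.pop()!r}, ref is {ref.busco_gene!r}")
    if genome is None:
        if not genomes:
            raise ValueError("empty hit list needs an explicit genome name")
        genome = genomes.pop()

    retained = [h for h in hits if h.bit_score > ref.bitscore_cutoff]
    if not retained:
        status = "missing"
    else:
        full = [
            h
            for h in retained
            if h.aligned_length >= FULL_LENGTH_FRAC * ref.ref_aligned_length
        ]
        if not full:
            status = "fragmented"
        elif len(full) == 1:
            status = "complete"
        else:
            status = "duplicated"
    return GeneStatus(genome=genome, busco_gene=ref.busco_gene, status=status)


def classify_table(
    hits: Iterable[HitRecord],
    refs: Mapping[str, GeneRefStats],
    genomes: Iterable[str],
) -> List[GeneStatus]:
    """Classify every (genome, gene) pair; pairs with no hits are missing."""
    by_pair: Dict[tuple, List[HitRecord]] = {}
    for h in hits:
        by_pair.setdefault((h.genome, h.busco_gene), []).append(h)
    out = []
    for genome in genomes:
        for gene in sorted(refs):
            pair_hits = by_pair.get((genome, gene), [])
            out.append(classify_gene(pair_hits, refs[gene], genome=genome))
    return out


def summarize_genome(
    statuses: Iterable[GeneStatus],
    n_busco: int,
    stop_free: Optional[Mapping[str, bool]] = None,
) -> Dict[str, float]:
    """Completeness fractions for one genome, as percentages to one decimal.

    ``stop_free`` flags (from the codon module) mark which complete genes
    lack in-frame stops; the "phylo" count is the number of complete genes
    passing that screen (all of them if no flags are supplied).
    """
    statuses = list(statuses)
    if n_busco < 1:
        raise ValueError("n_busco must be >= 1")
    genomes = {s.genome for s in statuses}
    if len(genomes) != 1:
        raise ValueError("statuses must cover exactly one genome")
    seen = set()
    for s in statuses:
        key = (s.genome, s.busco_gene)
        if key in seen:
            raise ValueError(f"duplicate status for {key}")
        seen.add(key)

    counts = {st: 0 for st in STATUSES}
    for s in statuses:
        counts[s.status] += 1
    phylo = sum(
        1
        for s in statuses
        if s.status == "complete" and (stop_free is None or stop_free.get(s.busco_gene, True))
    )
    out = {"genome": genomes.pop()}
    for st in STATUSES:
        out[st] = counts[st]
        out[f"{st}_pct"] = round(100.0 * counts[st] / n_busco, 1)
    out["phylo"] = phylo
    out["phylo_pct"] = round(100.0 * phylo / n_busco, 1)
    return out


def read_hit_table(path) -> List[HitRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        HitRecord(
            genome=str(r.genome),
            busco_gene=str(r.busco_gene),
            candidate_id=str(r.candidate_id),
            bit_score=float(r.bit_score),
            aligned_length=int(r.aligned_length),
        )
        for r in df.itertuples()
    ]


def read_ref_stats(path) -> Dict[str, GeneRefStats]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.busco_gene): GeneRefStats(
            busco_gene=str(r.busco_gene),
            bitscore_cutoff=float(r.bitscore_cutoff),
            ref_aligned_length=int(r.ref_aligned_length),
        )
        for r in df.itertuples()
    }


def write_summary(summaries: Iterable[Mapping], path) -> pd.DataFrame:
    df = pd.DataFrame(list(summaries))
    df.to_csv(path, sep="\t", index=False)
    return df
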
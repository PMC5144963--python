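"""Supermatrix concatenation, occupancy statistics and writers.

Per-gene alignments (amino-acid or first/second-codon-position
nucleotide, "C12") are concatenated into one character matrix over a
fixed taxon universe.  A taxon absent from a gene has that gene's
partition filled with '?' (absence, distinct from the within-alignment
'-' indel gap).  Genes are concatenated in lexicographic name order so
output is reproducible; partition coordinates are 0-based half-open
internally and 1-based inclusive in emitted partition files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import pandas as pd

from .codons import Alignment

__all__ = [
    "Supermatrix",
    "concatenate",
    "occupancy_report",
    "write_phylip",
    "read_phylip",
    "write_partitions",
    "read_partitions",
    "write_supermatrix_fasta",
]

MISSING_CHAR = "?"
PARTITION_MODELS = {"AA": "LG", "C12": "GTR"}


@dataclass
class Supermatrix:
    kind: str  # "AA" or "C12"
    taxa: List[str]
    columns: int
    rows: Dict[str, str]
    partitions: Dict[str, Tuple[int, int]]  # gene -> [start, end)
    gene_occupancy: Dict[str, float]
    taxon_occupancy: Dict[str, float]

    def __post_init__(self):
        widths = sum(e - s for s, e in self.partitions.values())
        if widths != self.columns:
            raise ValueError("partition widths do not sum to column count")
        for t in self.taxa:
            if len(self.rows[t]) != self.columns:
                raise ValueError(f"row {t!r} has wrong length")


def concatenate(
    alns: Iterable[Alignment], taxa_universe: Iterable[str], kind: str = "AA"
) -> Supermatrix:
    """Concatenate per-gene alignments over a taxon universe.

    Raises on duplicate gene names or taxa outside the universe.  Per-gene
    occupancy is the fraction of the universe present in the gene;
    per-taxon occupancy is the fraction of genes in which the taxon has
    sequence.
    """
    if kind not in PARTITION_MODELS:
        raise ValueError(f"kind must be one of {sorted(PARTITION_MODELS)}")
    taxa = list(taxa_universe)
    universe = set(taxa)
    if len(universe) != len(taxa):
        raise ValueError("duplicate taxa in universe")
    by_gene = {}
    for aln in alns:
        if aln.gene in by_gene:
            raise ValueError(f"duplicate gene name {aln.gene!r}")
        outside = set(aln.rows) - universe
        if outside:
            raise ValueError(f"{aln.gene}: taxa outside universe: {sorted(outside)}")
        by_gene[aln.gene] = aln

    genes = sorted(by_gene)
    parts: Dict[str, Tuple[int, int]] = {}
    chunks: Dict[str, List[str]] = {t: [] for t in taxa}
    start = 0
    gene_occ: Dict[str, float] = {}
    present_count = {t: 0 for t in taxa}
    for gene in genes:
        aln = by_gene[gene]
        width = aln.length
        parts[gene] = (start, start + width)
        start += width
        for t in taxa:
            if t in aln.rows:
                chunks[t].append(aln.rows[t])
                present_count[t] += 1
            else:
                chunks[t].append(MISSING_CHAR * width)
        gene_occ[gene] = len(aln.rows) / len(taxa)
    n_genes = len(genes)
    return Supermatrix(
        kind=kind,
        taxa=taxa,
        columns=start,
        rows={t: "".join(chunks[t]) for t in taxa},
        partitions=parts,
        gene_occupancy=gene_occ,
        taxon_occupancy={t: present_count[t] / n_genes if n_genes else 0.0 for t in taxa},
    )


def occupancy_report(m: Supermatrix) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, float]]:
    """Per-gene and per-taxon occupancy tables plus a summary.

    Percentages are reported to one decimal; lengths are partition widths
    (residues for AA, bp for C12/codon matrices).
    """
    gene_df = pd.DataFrame(
        {
            "gene": list(m.partitions),
            "length": [e - s for s, e in m.partitions.values()],
            "occupancy_pct": [round(100.0 * m.gene_occupancy[g], 1) for g in m.partitions],
        }
    )
    taxon_df = pd.DataFrame(
        {
            "taxon": m.taxa,
            "n_genes_present": [
                round(m.taxon_occupancy[t] * len(m.partitions)) for t in m.taxa
            ],
            "occupancy_pct": [round(100.0 * m.taxon_occupancy[t], 1) for t in m.taxa],
        }
    )
    occ = gene_df["occupancy_pct"]
    lens = gene_df["length"]
    summary = {
        "n_genes": len(gene_df),
        "n_taxa": len(m.taxa),
        "columns": m.columns,
        "min_occupancy_pct": float(occ.min()) if len(occ) else float("nan"),
        "max_occupancy_pct": float(occ.max()) if len(occ) else float("nan"),
        "mean_occupancy_pct": round(float(occ.mean()), 1) if len(occ) else float("nan"),
        "min_length": int(lens.min()) if len(lens) else 0,
        "max_length": int(lens.max()) if len(lens) else 0,
        "mean_length": round(float(lens.mean()), 1) if len(lens) else 0.0,
    }
    return gene_df, taxon_df, summary


def write_phylip(m: Supermatrix, path) -> None:
    """Relaxed PHYLIP: name and sequence separated by two spaces."""
    with open(path, "w") as fh:
        fh.write(f"{len(m.taxa)} {m.columns}\n")
        for t in m.taxa:
            fh.write(f"{t}  {m.rows[t]}\n")


def read_phylip(path, kind: str, partitions: Dict[str, Tuple[int, int]]) -> Supermatrix:
    with open(path) as fh:
        header = fh.readline().split()
        n_taxa, n_cols = int(header[0]), int(header[1])
        taxa, rows = [], {}
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            taxa.append(name)
            rows[name] = seq.strip()
    if len(taxa) != n_taxa or any(len(s) != n_cols for s in rows.values()):
        raise ValueError("malformed PHYLIP file")
    n_genes = len(partitions)
    gene_occ = {}
    present = {t: 0 for t in taxa}
    for g, (s, e) in partitions.items():
        n_present = 0
        for t in taxa:
            if set(rows[t][s:e]) != {MISSING_CHAR}:
                n_present += 1
                present[t] += 1
        gene_occ[g] = n_present / len(taxa)
    return Supermatrix(
        kind=kind,
        taxa=taxa,
        columns=n_cols,
        rows=rows,
        partitions=dict(partitions),
        gene_occupancy=gene_occ,
        taxon_occupancy={t: present[t] / n_genes if n_genes else 0.0 for t in taxa},
    )


def write_partitions(m: Supermatrix, path) -> None:
    """RAxML-style partition file, 1-based inclusive coordinates."""
    model = PARTITION_MODELS[m.kind]
    with open(path, "w") as fh:
        for gene, (s, e) in m.partitions.items():
            fh.write(f"{model}, {gene} = {s + 1}-{e}\n")


def read_partitions(path) -> Dict[str, Tuple[int, int]]:
    parts = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            _, rest = line.split(",", 1)
            gene, span = rest.split("=")
            lo, hi = span.split("-")
            parts[gene.strip()] = (int(lo) - 1, int(hi))
    return parts


def write_supermatrix_fasta(m: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        for t in m.taxa:
            fh.write(f">{t}\n{m.rows[t]}\n")
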
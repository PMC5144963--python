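"""Quality filters for gene alignments and trees.

Three bespoke screens applied before matrix construction:

1. long-branch (spurious/paralogous) sequence removal — drop leaves whose
   terminal branch length is at least ``factor`` (default 20) times the
   median terminal branch length of that gene's phylogram;
2. minimum trimmed-alignment length (default 500 bp);
3. minimum taxon occupancy (default 50% of the taxon universe).

Sequence removal precedes the length/occupancy screens; the median is
computed once on the original tree, not recomputed after removals.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set, Tuple

import dendropy
import pandas as pd

from .codons import GAP_CODON, CodonAlignment

__all__ = [
    "FilterReport",
    "detect_long_branches",
    "apply_sequence_removal",
    "filter_gene_set",
    "write_filter_reports",
]

DEFAULT_FACTOR = 20.0
DEFAULT_MIN_LEN_BP = 500
DEFAULT_MIN_TAXA_FRAC = 0.5


class EmptyAlignmentError(ValueError):
    pass


@dataclass
class FilterReport:
    gene: str
    removed_taxa: Dict[str, Tuple[float, float]] = field(default_factory=dict)  # taxon -> (branch, median)
    trimmed_len: int = 0
    length_pass: bool = True
    n_taxa: int = 0
    taxon_threshold: int = 0
    occupancy_pass: bool = True
    excluded: bool = False

    @property
    def retained(self) -> bool:
        return self.length_pass and self.occupancy_pass and not self.excluded


def detect_long_branches(tree: dendropy.Tree, factor: float = DEFAULT_FACTOR) -> Set[str]:
    """Leaves whose terminal branch is >= factor x median terminal branch.

    The median is taken over all terminal branches of the original tree in
    a single pass (no iterative re-screening).  Scale-invariant: rescaling
    every branch length by a positive constant leaves the result unchanged.
    """
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 4:
        raise ValueError("need >= 4 leaves")
    lengths = {}
    for lf in leaves:
        if lf.edge.length is None:
            raise ValueError(f"leaf {lf.taxon.label!r} has no branch length")
        lengths[lf.taxon.label] = lf.edge.length
    med = statistics.median(lengths.values())
    return {t for t, ln in lengths.items() if ln >= factor * med}


def apply_sequence_removal(aln: CodonAlignment, remove: Iterable[str]) -> CodonAlignment:
    """Drop rows, then drop whole-codon columns left 100% gap.

    Dropping the only sequences with data in a codon column leaves an
    all-gap column that carries no signal; those columns are removed so the
    reported trimmed length reflects usable sites.
    """
    remove = set(remove)
    extra = remove - set(aln.rows)
    if extra:
        raise ValueError(f"{aln.gene}: taxa not in alignment: {sorted(extra)}")
    rows = {t: s for t, s in aln.rows.items() if t not in remove}
    if not rows:
        raise EmptyAlignmentError(f"{aln.gene}: removal would empty the alignment")
    if not remove:
        return CodonAlignment(gene=aln.gene, rows=dict(rows), codes=dict(aln.codes))
    n_codons = aln.length // 3
    keep_codons = [
        i
        for i in range(n_codons)
        if any(s[3 * i : 3 * i + 3] != GAP_CODON for s in rows.values())
    ]
    new_rows = {
        t: "".join(s[3 * i : 3 * i + 3] for i in keep_codons) for t, s in rows.items()
    }
    codes = {t: c for t, c in aln.codes.items() if t in new_rows}
    return CodonAlignment(gene=aln.gene, rows=new_rows, codes=codes)


def filter_gene_set(
    alns: Iterable[CodonAlignment],
    total_taxa: int,
    min_len_bp: int = DEFAULT_MIN_LEN_BP,
    min_taxa_frac: float = DEFAULT_MIN_TAXA_FRAC,
    excluded_genes: Iterable[str] = (),
    reports: Dict[str, FilterReport] | None = None,
) -> Tuple[List[CodonAlignment], List[FilterReport]]:
    """Retain genes meeting the length and occupancy thresholds.

    The occupancy threshold is ``ceil(min_taxa_frac * total_taxa)`` taxa
    (48 at the defaults for a 96-taxon universe: alignments with fewer
    than 48 taxa are dropped).  ``reports`` may carry per-gene
    :class:`FilterReport` objects from the removal stage to be completed
    in place.
    """
    if total_taxa < 4:
        raise ValueError("total_taxa must be >= 4")
    excluded = set(excluded_genes)
    threshold = math.ceil(min_taxa_frac * total_taxa)
    retained: List[CodonAlignment] = []
    out_reports: List[FilterReport] = []
    for aln in alns:
        rep = (reports or {}).get(aln.gene) or FilterReport(gene=aln.gene)
        rep.trimmed_len = aln.length
        rep.n_taxa = len(aln.rows)
        rep.taxon_threshold = threshold
        rep.excluded = aln.gene in excluded
        rep.length_pass = aln.length >= min_len_bp
        rep.occupancy_pass = len(aln.rows) >= threshold
        out_reports.append(rep)
        if rep.retained:
            retained.append(aln)
    return retained, out_reports


def write_filter_reports(reports: Iterable[FilterReport], path) -> pd.DataFrame:
    recs = []
    for r in reports:
        if r.removed_taxa:
            for taxon, (ln, med) in sorted(r.removed_taxa.items()):
                recs.append(
                    dict(gene=r.gene, taxon=taxon, terminal_length=ln,
                         median_length=med, action="sequence_removed")
                )
        action = "retained" if r.retained else (
            "excluded" if r.excluded else
            "dropped_short" if not r.length_pass else "dropped_occupancy"
        )
        recs.append(
            dict(gene=r.gene, taxon="", terminal_length=float("nan"),
                 median_length=float("nan"), action=action)
        )
    df = pd.DataFrame(recs)
    df.to_csv(path, sep="\t", index=False)
    return df
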
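"""End-to-end orchestration: hits -> status -> screen -> filter -> matrices.

``run_pipeline`` consumes a directory of per-gene codon alignments and
gene trees plus BUSCO-style hit tables (the layout written by
:func:`buscophylo.synth.write_dataset`), applies the completeness
classification, stop-codon screen, long-branch removal and
length/occupancy filters, builds the AA and C12 supermatrices, and
writes a manifest of per-stage counts.  Re-running on identical inputs
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import busco, codons, filters, supermatrix, treesignal
from .codons import CodonAlignment
from .trees import read_newick

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    data_dir: str
    out_dir: str
    factor: float = 20.0
    min_len_bp: int = 500
    min_taxa_frac: float = 0.5
    excluded_genes: List[str] = field(default_factory=list)
    top_fracs: List[float] = field(default_factory=lambda: [0.5, 0.25])
    ic_mode: str = "IC"
    ica_threshold: float = 0.05
    reference_tree: Optional[str] = None  # newick; IC annotation if given
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        d = Path(self.data_dir)
        for sub in ("genes", "trees"):
            if not (d / sub).is_dir():
                raise PipelineError("config", f"missing directory {d / sub}")
        for name in ("hits.tsv", "ref_stats.tsv", "taxa.txt"):
            if not (d / name).is_file():
                raise PipelineError("config", f"missing file {d / name}")
        if self.factor <= 0 or self.min_len_bp < 0 or not (0 < self.min_taxa_frac <= 1):
            raise PipelineError("config", "filter parameters out of range")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Dict:
    """Run all stages; returns the manifest (also written as JSON)."""
    cfg.validate()
    data = Path(cfg.data_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    taxa = [ln.strip() for ln in open(data / "taxa.txt") if ln.strip()]
    cug_path = data / "cug_ser_taxa.txt"
    cug = (
        {ln.strip() for ln in open(cug_path) if ln.strip()} if cug_path.exists() else set()
    )

    # --- completeness classification -------------------------------------
    log.info("stage classify: reading hit tables")
    hits = busco.read_hit_table(data / "hits.tsv")
    refs = busco.read_ref_stats(data / "ref_stats.tsv")
    statuses = busco.classify_table(hits, refs, taxa)

    # --- alignments + stop screen ----------------------------------------
    log.info("stage screen: reading alignments and screening stops")
    alns: Dict[str, CodonAlignment] = {}
    stop_free: Dict[str, Dict[str, bool]] = {g: {} for g in taxa}
    for fasta in sorted((data / "genes").glob("*.fasta")):
        gene = fasta.stem
        rows = codons.read_fasta(fasta)
        code_map = {t: ("cug_ser" if t in cug else "standard") for t in rows}
        try:
            aln = CodonAlignment(gene=gene, rows=rows, codes=code_map)
        except ValueError as e:
            raise PipelineError("screen", str(e)) from e
        keep_rows = {}
        for taxon, seq in rows.items():
            # gaps are whole-codon triples, so degapping preserves frame
            ok = not codons.has_inframe_stop(seq.replace("-", ""), aln.code_for(taxon))
            stop_free[taxon][gene] = ok
            if ok:
                keep_rows[taxon] = seq
        alns[gene] = CodonAlignment(
            gene=gene, rows=keep_rows,
            codes={t: code_map[t] for t in keep_rows},
        )

    per_genome = []
    by_genome: Dict[str, list] = {t: [] for t in taxa}
    for s in statuses:
        by_genome[s.genome].append(s)
    for genome in taxa:
        per_genome.append(
            busco.summarize_genome(by_genome[genome], len(refs), stop_free[genome])
        )
    busco.write_summary(per_genome, out / "busco_summary.tsv")

    # --- long-branch removal ---------------------------------------------
    log.info("stage longbranch: screening gene trees")
    reports: Dict[str, filters.FilterReport] = {}
    cleaned: List[CodonAlignment] = []
    n_removed_seqs = 0
    for gene in sorted(alns):
        aln = alns[gene]
        rep = filters.FilterReport(gene=gene)
        tree_path = data / "trees" / f"{gene}.nwk"
        if tree_path.exists() and len(aln.rows) >= 4:
            tree = read_newick(tree_path)
            import statistics as _st

            lengths = {
                lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
            }
            med = _st.median(lengths.values())
            try:
                rogues = filters.detect_long_branches(tree, cfg.factor)
            except ValueError as e:
                raise PipelineError("longbranch", f"{gene}: {e}") from e
            rogues &= set(aln.rows)
            rep.removed_taxa = {t: (lengths[t], med) for t in sorted(rogues)}
            n_removed_seqs += len(rogues)
            if rogues:
                try:
                    aln = filters.apply_sequence_removal(aln, rogues)
                except filters.EmptyAlignmentError as e:
                    raise PipelineError("longbranch", str(e)) from e
        reports[gene] = rep
        cleaned.append(aln)

    # --- length / occupancy filters --------------------------------------
    retained, report_list = filters.filter_gene_set(
        cleaned,
        total_taxa=len(taxa),
        min_len_bp=cfg.min_len_bp,
        min_taxa_frac=cfg.min_taxa_frac,
        excluded_genes=cfg.excluded_genes,
        reports=reports,
    )
    filters.write_filter_reports(report_list, out / "filter_report.tsv")

    # --- matrices ----------------------------------------------------------
    log.info("stage matrices: building AA and C12 supermatrices")
    codons.write_gc_report(retained, out / "gc_report.tsv")
    aa_alns = [codons.translate_alignment(a) for a in retained]
    c12_alns = [codons.extract_c12(a) for a in retained]
    aa = supermatrix.concatenate(aa_alns, taxa, kind="AA")
    c12 = supermatrix.concatenate(c12_alns, taxa, kind="C12")
    for m, prefix in ((aa, "aa"), (c12, "c12")):
        supermatrix.write_phylip(m, out / f"{prefix}_matrix.phy")
        supermatrix.write_partitions(m, out / f"{prefix}_partitions.txt")
        gene_df, taxon_df, _ = supermatrix.occupancy_report(m)
        gene_df.to_csv(out / f"{prefix}_gene_occupancy.tsv", sep="\t", index=False)
        taxon_df.to_csv(out / f"{prefix}_taxon_occupancy.tsv", sep="\t", index=False)

    # --- optional IC annotation -------------------------------------------
    mean_ic = None
    if cfg.reference_tree:
        log.info("stage signal: annotating IC on reference tree")
        ref = read_newick(cfg.reference_tree)
        retained_genes = {a.gene for a in retained}
        gene_trees = [
            read_newick(data / "trees" / f"{g}.nwk")
            for g in sorted(retained_genes)
            if (data / "trees" / f"{g}.nwk").exists()
        ]
        values, mean_ic = treesignal.annotate_ic(
            ref, gene_trees, mode=cfg.ic_mode, ica_threshold=cfg.ica_threshold
        )
        with open(out / "internode_ic.tsv", "w") as fh:
            fh.write("block_a\tic\n")
            for bip in sorted(values, key=lambda b: sorted(b.block_a)):
                fh.write(f"{','.join(sorted(bip.block_a))}\t{values[bip]:.3f}\n")

    import math as _m

    taxon_threshold = _m.ceil(cfg.min_taxa_frac * len(taxa))
    genes_in = len(alns)
    manifest = {
        "parameters": {
            "factor": cfg.factor,
            "min_len_bp": cfg.min_len_bp,
            "min_taxa_frac": cfg.min_taxa_frac,
            "taxon_threshold": taxon_threshold,
            "excluded_genes": sorted(cfg.excluded_genes),
            "seed": cfg.seed,
        },
        "inputs": {
            "hits_sha256": _sha256(data / "hits.tsv"),
            "ref_stats_sha256": _sha256(data / "ref_stats.tsv"),
            "n_taxa": len(taxa),
        },
        "counts": {
            "genes_in": genes_in,
            "genes_retained": len(retained),
            "genes_dropped": genes_in - len(retained),
            "sequences_removed": n_removed_seqs,
            "aa_columns": aa.columns,
            "c12_columns": c12.columns,
        },
    }
    if mean_ic is not None:
        manifest["counts"]["mean_ic"] = mean_ic
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
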
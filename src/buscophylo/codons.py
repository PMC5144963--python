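"""Genetic-code-aware codon handling.

Covers translation under the standard and CUG-Ser codes (the yeast
CUG-Ser clade reads CTG as serine rather than leucine), in-frame stop
screening, threading unaligned coding sequence onto an amino-acid
alignment to produce a codon-based alignment, first/second codon position
(C12) extraction, and GC content by codon position.

Code tables come from the NCBI tables shipped with Biopython: table 1
(standard) and table 12 (alternative yeast nuclear, CTG -> Ser).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "STANDARD",
    "CUG_SER",
    "GENETIC_CODES",
    "Alignment",
    "CodonAlignment",
    "FrameError",
    "InFrameStopError",
    "ThreadingError",
    "translate",
    "has_inframe_stop",
    "thread_codons",
    "extract_c12",
    "gc_by_codon_position",
    "read_fasta",
    "write_fasta",
]

GAP_CODON = "---"
_NUCS = set("ACGT")


class FrameError(ValueError):
    """Sequence length is not a multiple of three."""


class InFrameStopError(ValueError):
    """An in-frame stop codon was found where none is allowed."""


class ThreadingError(ValueError):
    """CDS does not back-translate onto the amino-acid alignment row."""


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon -> amino-acid map with stops marked '*'."""

    name: str
    table: Mapping[str, str]
    stops: frozenset

    @staticmethod
    def from_ncbi(name: str, table_id: int) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(t.forward_table)
        for stop in t.stop_codons:
            mapping[stop] = "*"
        return GeneticCode(name=name, table=mapping, stops=frozenset(t.stop_codons))

    def __getitem__(self, codon: str) -> str:
        return self.table[codon]


STANDARD = GeneticCode.from_ncbi("standard", 1)
CUG_SER = GeneticCode.from_ncbi("cug_ser", 12)
GENETIC_CODES: Dict[str, GeneticCode] = {"standard": STANDARD, "cug_ser": CUG_SER}


@dataclass
class Alignment:
    """A named set of equal-length aligned rows (amino acid or nucleotide)."""

    gene: str
    rows: Dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene}: unequal row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def taxa(self):
        return list(self.rows)


@dataclass
class CodonAlignment(Alignment):
    """In-frame codon-based nucleotide alignment with per-taxon code names.

    Gaps occur only as whole-codon '---' triples; the alignment length is a
    multiple of three.
    """

    codes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        super().__post_init__()
        if self.length % 3 != 0:
            raise FrameError(f"{self.gene}: length {self.length} not a codon multiple")
        for taxon, seq in self.rows.items():
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if "-" in codon and codon != GAP_CODON:
                    raise ValueError(
                        f"{self.gene}/{taxon}: partial-codon gap {codon!r} at nt {i}"
                    )
        for taxon in self.rows:
            self.codes.setdefault(taxon, "standard")

    def code_for(self, taxon: str) -> GeneticCode:
        return GENETIC_CODES[self.codes.get(taxon, "standard")]


def _codons(seq: str):
    if len(seq) % 3 != 0:
        raise FrameError(f"length {len(seq)} is not a multiple of 3")
    for i in range(0, len(seq), 3):
        yield i // 3, seq[i : i + 3]


def translate(seq: str, code: GeneticCode = STANDARD) -> str:
    """Translate an in-frame nucleotide sequence to amino acids.

    '---' becomes '-'; any codon containing a non-ACGT character becomes
    'X'; a stop codon (terminal or internal) raises
    :class:`InFrameStopError`, matching the pipeline's policy of using only
    stop-free coding sequences.
    """
    seq = seq.upper()
    out = []
    for idx, codon in _codons(seq):
        if codon == GAP_CODON:
            out.append("-")
        elif "-" in codon:
            raise ValueError(f"partial-codon gap {codon!r} at codon {idx}")
        elif not set(codon) <= _NUCS:
            out.append("X")
        elif codon in code.stops:
            raise InFrameStopError(f"stop codon {codon} at codon {idx}")
        else:
            out.append(code[codon])
    return "".join(out)


def has_inframe_stop(seq: str, code: GeneticCode = STANDARD) -> bool:
    """True iff any codon (terminal included) is a stop under ``code``."""
    seq = seq.upper()
    return any(codon in code.stops for _, codon in _codons(seq))


def thread_codons(
    aa_aln: Alignment,
    cds: Mapping[str, str],
    codes: Mapping[str, str] | None = None,
) -> CodonAlignment:
    """Map unaligned CDS onto an amino-acid alignment (back-translation).

    Each aligned residue is replaced by its source codon and each '-' by
    '---'.  The CDS must translate, under the taxon's genetic code, to the
    degapped alignment row; any mismatch raises :class:`ThreadingError`
    naming the taxon and alignment column.
    """
    codes = dict(codes or {})
    rows: Dict[str, str] = {}
    for taxon, aa_row in aa_aln.rows.items():
        if taxon not in cds:
            raise ThreadingError(f"no CDS for taxon {taxon!r}")
        code = GENETIC_CODES[codes.get(taxon, "standard")]
        nt = cds[taxon].upper()
        aa = translate(nt, code)
        out = []
        pos = 0
        for col, residue in enumerate(aa_row):
            if residue == "-":
                out.append(GAP_CODON)
                continue
            if pos >= len(aa) or aa[pos] != residue:
                raise ThreadingError(
                    f"{aa_aln.gene}/{taxon}: CDS residue "
                    f"{aa[pos] if pos < len(aa) else '<end>'} != alignment "
                    f"residue {residue} at column {col}"
                )
            out.append(nt[3 * pos : 3 * pos + 3])
            pos += 1
        if pos != len(aa):
            raise ThreadingError(f"{aa_aln.gene}/{taxon}: {len(aa) - pos} unused codons")
        rows[taxon] = "".join(out)
    return CodonAlignment(gene=aa_aln.gene, rows=rows, codes=codes)


def translate_alignment(codon_aln: CodonAlignment) -> Alignment:
    """Column-wise translation of a codon alignment (round-trip partner)."""
    return Alignment(
        gene=codon_aln.gene,
        rows={t: translate(s, codon_aln.code_for(t)) for t, s in codon_aln.rows.items()},
    )


def extract_c12(codon_aln: CodonAlignment) -> Alignment:
    """Keep first and second positions of every codon (drop third).

    Output length is 2/3 of the codon alignment; gap codons yield '--'.
    Third positions are the usual casualty of compositional heterogeneity
    (their GC content varies far more across taxa than positions 1-2).
    """
    rows = {}
    for taxon, seq in codon_aln.rows.items():
        rows[taxon] = "".join(
            seq[i] for i in range(len(seq)) if i % 3 != 2
        )
    return Alignment(gene=codon_aln.gene, rows=rows)


def gc_by_codon_position(codon_aln: CodonAlignment) -> Tuple[float, float, float]:
    """GC fraction at codon positions 1, 2, 3 over unambiguous non-gap sites.

    Returns NaN for a position class with no countable characters.
    """
    gc = [0, 0, 0]
    total = [0, 0, 0]
    for seq in codon_aln.rows.values():
        for i, ch in enumerate(seq):
            if ch in _NUCS:
                p = i % 3
                total[p] += 1
                if ch in "GC":
                    gc[p] += 1
    return tuple(gc[p] / total[p] if total[p] else float("nan") for p in range(3))


def write_gc_report(codon_alns, path) -> None:
    """TSV of per-gene GC fraction at codon positions 1, 2, 3."""
    with open(path, "w") as fh:
        fh.write("gene\tgc1\tgc2\tgc3\n")
        for aln in codon_alns:
            g1, g2, g3 = gc_by_codon_position(aln)
            fh.write(f"{aln.gene}\t{g1:.4f}\t{g2:.4f}\t{g3:.4f}\n")


def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(rows: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in rows:
            fh.write(f">{name}\n{rows[name]}\n")
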
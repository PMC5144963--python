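# Methods

## Completeness classification

Each genome × BUSCO-gene combination is classified from its candidate
hits. Hits are retained when their bit-score is strictly greater than
the gene's cutoff (supplied as reference metadata; by convention 90% of
the lowest bit-score among reference genomes). No retained hit gives
`missing`; all retained hits shorter than 95% of the reference aligned
length give `fragmented`; otherwise one full-length hit gives
`complete` and two or more give `duplicated`. Both comparisons are
strict on the failing side, so a hit at exactly the cutoff is discarded
while a hit at exactly 95% of the reference length counts as
full-length. The upstream homology search itself (profile HMMs,
tBLASTn, gene prediction) is out of scope; the classifier consumes its
tabulated output. Percentages are reported to one decimal
(round-half-even), and the `phylo` count restricts `complete` genes to
those whose coding sequence is free of in-frame stop codons under the
taxon's genetic code.

## Genetic codes and codon handling

Code tables come from the NCBI tables shipped with Biopython: table 1
(standard) and table 12 (CTG → Ser), which differ at exactly one codon
and share the three stops. Translation maps `---` to `-`, any codon
containing a non-ACGT character to `X` (the handling of ambiguity codes
is this package's convention), and raises on any stop codon, terminal
ones included — the pipeline's filter admits only entirely stop-free
sequences. Codon alignments are produced by threading unaligned CDS
onto an amino-acid alignment (each residue replaced by its source
codon, each gap by `---`), which guarantees whole-codon gaps by
construction; inputs violating that invariant are rejected rather than
repaired. Column-wise translation of a threaded alignment reproduces
the amino-acid alignment exactly, a property the test suite checks on
arbitrary inputs. The C12 extraction keeps codon positions 1 and 2, so
C12 site counts are exactly twice the amino-acid site counts for any
gene set. GC content per codon position is computed over unambiguous
non-gap characters only, returning NaN for an empty position class;
this is the diagnostic that motivates excluding third positions from
the nucleotide matrix.

## Quality filters

Long-branch screening computes the median terminal branch length of a
gene's phylogram once and removes every leaf whose terminal branch is
at least `factor` (default 20) times that median — a single pass, not
an iterative one, and inclusive at the threshold. The test suite checks
scale invariance (rescaling all branch lengths changes nothing) and
exact recovery of generator-injected rogues. After row removal, codon
columns left entirely gapped are dropped, so the reported trimmed
length counts only usable sites. Gene-level screens then require
trimmed length ≥ 500 bp and taxon count ≥ `ceil(frac × total_taxa)`
(48 at the defaults for 96 taxa); both predicates are evaluated on the
post-removal alignment, so their order is immaterial. Genes may also be
excluded by name, which is how a known-bad family is dropped without a
special case. Gene trees are not re-inferred after sequence removal;
tree inference is outside this package.

## Supermatrices

Genes are concatenated in lexicographic name order over a fixed taxon
universe. A taxon absent from a gene has that gene's partition filled
with `?`, kept distinct from the within-alignment indel gap `-` because
downstream inference tools treat absence and indels differently.
Partition coordinates are 0-based half-open internally and 1-based
inclusive in the emitted RAxML-style partition file, whose model
strings (`LG` for AA, `GTR` for C12) are metadata only — no model
fitting happens here. Occupancy is accounted both per gene (taxa
present / universe) and per taxon (genes present / gene count); the two
marginal totals must agree, and a round-trip through the relaxed-PHYLIP
writer and reader reproduces rows, order and partitions exactly.

## Internode certainty over partial gene trees

All conflict computation reduces to bipartitions — the two-block
splits of the taxon set induced by internal edges — with a canonical
block order so equality is well defined. A gene tree on a taxon subset
is *informative* for a reference bipartition when the bipartition
restricted to the tree's taxa still has two taxa on each side.
Among informative trees, those containing the restricted reference
count as support; in the others, every bipartition incompatible with
the restricted reference is tallied. Conflicting splits observed on
different taxon subsets are pooled into *restriction-compatibility
classes*: a split joins an existing class when it agrees with the class
representative on their shared taxa (the representative is kept
maximal). Without this pooling, one underlying conflict fragments into
many small classes whenever taxa are missing at random, and IC is
overestimated; with it, frequencies behave consistently under deletion
of uninvolved taxa, which the suite tests directly. Frequencies are the
raw counts over informative trees. The exact lossless partial-tree
frequency adjustment described in the literature on adjusted internode
certainty is a noted alternative; it is not the default here, and mean
IC values from real partial-tree collections are expected to be
somewhat sensitive to this choice.

IC uses the reference count and the single most prevalent conflict;
ICA uses the reference plus all conflicts with frequency at least 5% of
the informative-tree count (a flag; unbounded tail inclusion makes ICA
degenerate with many near-zero splits), with logarithm base k+1 for k+1
retained frequencies. Values are negated when the reference is not the
most frequent split considered; no observed conflict gives 1, and an
internode with no informative trees is undefined (NaN) and excluded
from mean IC, which is printed to three decimals.

ABS is the mean, over a gene tree's internal edges, of the percentage
of bootstrap replicates containing each edge's (restricted) split; RTC
is the mean IC over those edges with frequencies drawn from the
replicates. Gene ranking sorts by score descending with
lexicographic-name tie-breaks and takes `floor(frac × n)` genes, so the
616/308 subset sizes at n = 1233 follow. Conflict counting between two
binary trees on one leaf set is the set difference of their
bipartitions (half the Robinson–Foulds distance; checked against
dendropy's implementation). The multilocus bootstrap draws one tree per
gene per replicate, uniformly with replacement, independently across
genes and replicates, deterministic under a fixed seed.

## Synthetic data

The generator's job is controlled pathology, not realism. Species trees
are built by uniform random joins with lognormal branch lengths
(terminal median 0.12, σ = 0.25; internal median 0.05, σ = 0.5).
Terminal lengths are deliberately narrowly dispersed so that a rogue
branch scaled 40× sits far above the 20×-median detection threshold
while background variation stays far below it — real phylograms have
heavier rate variation, so recovery rates measured here are an upper
bound on what the filter achieves in practice.

Discordance is a single NNI applied, in discordant genes, around one
designated internal edge (the same edge and exchange for all of them).
This trades realism (no coalescent process, no multi-edge conflict) for
exact control: the designated edge's IC follows the two-way closed form
1 − H₂(q) at discordance rate q, and every other internode stays at
IC = 1, which is what validates the IC machinery. Missing taxa are
dropped independently per gene at the configured rate, redrawing if
fewer than four leaves would remain (bipartitions are undefined below
four). Sequences evolve by i.i.d. per-nucleotide Jukes–Cantor
substitution along branches, with codons that become stops resampled;
there is no rate heterogeneity, selection or indel process, so these
alignments exercise translation, threading and matrix plumbing, not
model fit. CUG-Ser taxa are guaranteed at least one CTG codon so
code-aware translation is always exercised. Hit tables are constructed
backwards from drawn labels (default mix: 90% complete, 3% duplicated,
4% fragmented, 3% missing — chosen to resemble a well-assembled genome
set), so classifier output can be compared to truth exactly.

Bootstrap tree sets are perturbed-tree samples: each replicate applies
Binomial(4, 1 − q) random NNIs to the gene tree, where q is the gene's
sharpness. This does not attempt fidelity to rapid-bootstrap
resampling of alignment columns; it only provides the monotone link
between gene quality, ABS/RTC and topological accuracy that the
signal-enrichment analyses need. The heterogeneous-signal dataset draws
q uniformly per gene and couples it to both the gene tree's distance
from the species tree and its bootstrap sharpness, which is the
mechanism by which selecting top-ABS genes raises mean IC.

Defaults mirror the study shape the package targets: 96 taxa, 1233
genes, codon alignments of 167–4854 codons (501–14,562 bp), 10%
missing-taxon rate (≈90% mean occupancy), 3% of genes carrying one
rogue at 40× branch scaling. Identical configuration and seed give
byte-identical FASTA/newick/TSV/JSON outputs.

## Problem sizes in tests and the acceptance script

Unit tests run on 8–16-taxon, tens-of-genes datasets. The acceptance
script works at the study's matrix shape where the quantity demands it
(96 taxa and 93 internodes; 1233 genes; 609,899 AA sites built from the
study's gene-length range on a 6-taxon universe) and at reduced shape
where only a rate or an ordering is being measured (rogue recovery on
200 genes with 167–600-codon alignments, since the branch-length filter
never reads the sequences; signal enrichment on 32 taxa × 80 genes ×
50 replicates). Exhaustive bipartition checks enumerate all 1,068
unrooted binary topologies on 4–7 leaves against a brute-force oracle.

## Known limitations

* Alignment inference and trimming, ML tree search, model selection and
  species-tree estimation are all external to this package; it consumes
  and produces their file formats only.
* The partial-IC frequency adjustment is the observed-count variant
  described above, not the exact lossless correction.
* The evolutionary simulator is intentionally minimal; it cannot be
  used to benchmark substitution-model fit, saturation or
  long-branch-attraction artefacts beyond the terminal-length screen it
  was built to exercise.
* Only the standard and CUG-Ser codes are registered, though the code
  table is pluggable.
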
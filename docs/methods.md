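# Methods

This note documents the models, statistics and design choices behind
`gps-periscan`, in the order the pipeline runs them.

## Coordinates and formats

All intervals are 0-based, half-open internally; 1-based inclusive
coordinates appear only in human-readable report strings (matching genome
browsers). FASTA, BED3/BED6 and bedGraph readers are strict: malformed
records fail with the offending line number rather than being skipped.
bedGraph records must be non-overlapping per chromosome — the signal tracks
consumed here are fold-change-over-control tracks, not fragment piles, so an
overlap indicates a malformed file rather than something to sum. Genome FASTA
may contain N; ORFs may not span N.

## Candidate-locus scan

A candidate pericentromeric locus is the intersection of three masks:

* an **H3K27ac peak**: a maximal run of track signal ≥ `h3k27ac_threshold`
  (default 2.0 fold change), with runs separated by < `peak_merge_gap`
  (100 bp) merged and merged runs < `peak_min_width` (200 bp) dropped;
* an annotated **repeat** interval;
* a **pericentromeric window**: up to `flank` bp on either side of the
  centromere, excluding the centromere itself and clipped to the chromosome.

The original observations were read by eye from browser tracks; these
thresholds are declared defaults that make the judgement reproducible, not
values inferred from data. `flank` defaults to 50 kb at the package's toy
scale and should be raised (≈ 2 Mb) for full-size genomes. Candidates are
clipped to window ∩ repeat, then padded by `candidate_padding` (1 kb) before
ORF search so a peak edge cannot truncate an ORF. Each candidate records the
maximum H3K27ac and H3K27me3 over its span; **competence** (both marks at or
above threshold) is a flag, not a filter, because a locus can be competent in
one cell line and bare in another. Raising the H3K27ac threshold can only
shrink the candidate set (monotonicity, property-tested).

## ORF discovery and protein annotation

Six reading frames are scanned (three per strand). Within each stop-delimited
segment the reported ORF runs from the **most upstream qualifying start
codon** to the stop — the "maximum ORF length" convention of six-frame ORF
finders. The start-codon set defaults to {ATG, CTG, GTG, TTG}; published
tools vary in their alternative-initiation sets, so the set is explicit
configuration. Minimum ORF length defaults to 300 nt (stop included), which
filters repeat noise while passing both principal family ORFs (624 and
792 nt). ORFs containing N are rejected rather than ambiguously translated.
Nested ORFs on opposite strands are both reported. The implementation is
verified against a brute-force start/stop pair-enumeration oracle on random
sequences and satisfies reverse-complement symmetry.

Translation uses the standard genetic code; alternative initiation codons are
rendered as Met at position 1 (initiator-tRNA convention). The length
identity `nt_length = 3 × (protein length + 1)` holds for every reported ORF.

Protein annotation reports:

* **approximate molecular weight** = 0.110 kDa × residue count (the
  110-Da-per-average-residue rule used in the original annotations; the exact
  average-mass sum is reported as an auxiliary column);
* **isoelectric point** by bisection on [0, 14] to 0.01 pH of the
  Henderson–Hasselbalch net-charge sum over the termini and the D, E, C, Y,
  H, K, R side chains. The pKa table defaults to EMBOSS values and is
  swappable: published pI values for these proteins do not state their tool,
  and pI is pKa-set dependent (± ~0.3 between common sets), so exact
  reproduction of any printed pI is not claimed. Net charge is strictly
  decreasing in pH, so the root is unique; bisection is verified against a
  0.001-pH grid search.
* **residue enrichment**: per-residue fraction over a background (default
  uniform 0.05), with residues at ratio ≥ 1.5 flagged, descending.

## Intronless determination and mutation calling

Transcripts are aligned to their genomic reference by global affine-gap
alignment (match +2, mismatch −3, gap open −5 at the first gapped position,
extend −2; genomic end overhangs free). Genome-side gaps ≥ `intron_min_gap`
(20 nt) are candidate introns; a transcript is **intronless** when it has
none. Smaller gaps are treated as ordinary indels, separating splicing from
sequencing artefacts. Alignments below 70% identity (computed over aligned
columns excluding terminal overhang) are rejected as unconfident. Note that a
global aligner only prefers a long intron gap over mismatched read-through
when the downstream exon is long enough to pay for the gap; with the default
scoring, exons of a few dozen bases flanking a long intron can be absorbed as
mismatches. The synthetic spliced gene uses 240-nt exons, far inside the safe
regime.

Substitutions inside the ORF are grouped per codon (1-based, initiator
Met = codon 1; multiple substitutions in one codon give a single codon-level
call) and named `refAA + index + altAA`, with `(silent)` appended for
synonymous calls and `Stop` for stop-gains — e.g. `F42V`, `P129P (silent)`,
`G132Stop`. The nomenclature is bijective: the name is regenerable from the
fields. Indels inside the ORF raise a frameshift error, since the
substitution nomenclature does not cover them; polymorphism-versus-de-novo
status is deliberately not assigned. Two calls are *identical* across samples
iff their (codon index, alt codon) pairs match; catalogue comparison
partitions calls into shared (present in all samples) and per-sample unique
sets. For the earliest stop-gain at codon *s*, any motif hit starting at
position ≥ *s* is flagged as lost from the truncated product.

## Family homology

Homology runs pairwise rather than through a progressive multiple alignment:
the downstream readouts (identity-from-anchor matrices, average-linkage
cladograms) only need pairwise identities, and pairwise Needleman–Wunsch is
fully deterministic. Nucleotide scoring as above; protein scoring BLOSUM62
with gap open −11 / extend −1. Percent identity is computed from the
alignment (matches over aligned columns, terminal-gap columns excluded) and
is independent of the scoring matrix that produced the alignment.

UPGMA runs on distance = 100 − identity with deterministic tie-breaking
(lexicographically smallest label pair merges first); node heights are half
the merge distance, so the tree is ultrametric, and Newick output carries
branch lengths. The implementation is checked against an independent naive
UPGMA on random tables.

Conserved-window scanning slides windows of 12–13 residues (configurable)
along an anchor sequence (default: the first family member); a family member
*matches* a window if it contains a gapless segment at ≥ 10/12 identity, and
windows matched by ≥ 80% of the other members are hits, merged to maximal
spans. These cutoffs are declared choices — no published criterion exists for
the "conserved 12–13-residue window" observation. The FPFP scan reports every
exact, possibly overlapping occurrence of the 4-mer (1-based positions),
verified against a naive quadratic substring search.

## Expression statistics

* **MRSP** (maximum reads at a single point): the highest per-base depth over
  a gene's ORF — order-free and monotone under added reads. Input track units
  are taken as given.
* **combined score** (per gene): sum of MRSP across all cell lines;
  **GPS score** (per line): sum of MRSP over family genes. The two totals
  conserve the matrix grand total, which is asserted in tests.
* **Integration**: cumulative C19MC expression per line is the sum over a
  user-supplied member list (membership is an input, not hard-coded); lines
  sort by cumulative C19MC descending, ties by GPS score then line id.
* **Group selection**: positive group = top *n* (default 12) lines with
  C19MC > 0 and GPS score > 0; negative group = *n* lines with zero on both
  axes. "Positive" is operationalized as strictly > 0 because presence/absence
  is what the grouping uses; the cutoff is configurable. Selection is stable
  under re-running.
* **Differential expression**: on log2(x+1)-transformed values (the +1
  pseudocount handles the all-zero negative group), log2FC = difference of
  group means and p from a two-sided equal-variance Student's t-test —
  Student's rather than Welch because that is the named test. Flags require
  |log2FC| > 2 **and** p < 0.05; no multiple-testing correction by default
  (matching the original raw-p usage), with Benjamini–Hochberg available
  behind a flag. Genes with zero variance and equal means in both groups
  report p = 1.
* **ΔΔCt**: per sample ΔCt = Ct(target) − Ct(normalizer); ΔΔCt = mean
  treated − mean control; fold = 2^(−ΔΔCt), controls at 1 by construction.

## Synthetic data generator

The generator is first-class, tested code, and its defaults define the
study conditions used by the test suite:

* 3 chromosomes × 300 kb, one 30-kb centromere centred per chromosome, 50-kb
  repeat flanks on both sides — a seconds-scale caricature of a
  pericentromere.
* Repeat flanks are tandem arrays of a 171-bp satellite-like monomer with 1%
  per-base divergence between copies. The monomer carries two phases of the
  palindromic cassette `(TTAA)×3`, which contains TAA in all three frames of
  both strands, so stop codons recur every ≲ 100 nt in all six frames of the
  array — as in real higher-order satellite DNA, long ORFs cannot arise in
  the repeat background, and planted ORFs are recoverable at exactly their
  recorded coordinates.
* Four planted pericentromeric ORFs (624, 792, 450, 366 nt, mixed strands,
  centred in their repeat blocks) with an in-frame stop guard immediately
  upstream so the planted start codon is the segment's most upstream start.
  Proteins are random (the first one serine/threonine/tyrosine-biased, for
  the enrichment readout) with a shared 13-mer containing FPFP planted in
  each; nucleotide sequences draw synonymous codons uniformly. One decoy ORF
  and one spliced decoy gene (240+240-nt exons around a 100-nt GT…AG intron,
  boundary bases chosen to make the gap placement unambiguous) sit outside
  the flank.
* Signal tracks peak (amplitude 3.0, ORF ± 300 bp) over every planted
  pericentromeric ORF in both marks; background bins are uniform below half
  the calling threshold (exactly 0 in noise-free mode), guaranteeing
  threshold separation by construction rather than statistical tuning.
* Transcripts: per sample (default two, emulating two cell lines), a copy of
  each gene with 30 nt of genomic flank. The longest gene carries the planted
  mutation catalogue — shared F42V, P129P (silent) and G132Stop, plus one
  unique mutation per sample — with reference codons forced at those
  positions so each planted change is a real single-codon substitution.
* Expression: 100 cell lines; exactly 12 double-positive (highest cumulative
  C19MC and GPS > 0), exactly 12 double-zero, and the remainder positive on
  one axis only, so the grouping rule has a unique correct answer. The two
  longest genes are given the largest values so they top the combined scores.
  Twenty background genes carry planted log2 fold changes
  (±4, ±5, ±1.5, rest 0) at within-group sd 0.3 on the log2(x+1) scale.
* All generators are deterministic given a seed (byte-identical outputs) and
  consume independent streams derived from it; every downstream expectation
  is read from the serialized truth ledger, never re-derived from the data.

What the generator does **not** emulate: read-level sequencing (FASTQ),
error models, chromatin-state structure beyond single rectangular peaks,
realistic CCLE depth distributions (no published distribution exists for the
MRSP inputs, so the depth generator is a convenience, not a model claim),
linked-locus correlation structure, or population polymorphism. Passing
tests therefore demonstrate correctness of the computations and exact
ground-truth recovery under clean planted signal — not robustness to noisy,
confounded real data.

## Problem sizes and numerical choices

The test suite runs the full pipeline on ten seeds of the toy genome
(~0.9 Mb each) plus oracle-equivalence checks on short random inputs; the
whole suite completes in a few seconds on one CPU. Bisection tolerance for pI
is 0.01 pH against a 0.001 grid oracle. Alignment tie-breaks take the
aligner's first reported optimum, which is deterministic; UPGMA and sorting
tie-breaks are lexicographic. Degenerate inputs (empty profiles, zero-variance
genes, missing normalizers, mismatched line sets) raise errors or documented
fallbacks rather than propagating NaN.

## Known limitations

* The scan consumes signal tracks; peak calling from aligned reads is out of
  scope, as are TF co-binding statistics, database homology search,
  enrichment/network analysis and figure rendering.
* Genome-scale claims (the family's full membership across a real genome,
  cross-species homology sets) need real references and databases and are
  not reproduced at toy scale.
* Frameshift and indel nomenclature, chromatogram parsing and heterozygous
  base resolution are out of scope for mutation calling.
* The intron detector is a global aligner, not a splice-aware one; very short
  terminal exons can be mis-absorbed as mismatches (see above).
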
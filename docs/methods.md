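# Methods

This note documents the models, parameter choices, and numerical
conventions behind `nmcomp`, and what the simulation-based tests do and do
not demonstrate about real data.

## Coordinates and data model

All internal coordinates are 0-based half-open on the forward strand;
GenBank's 1-based inclusive convention is converted at the I/O boundary
(Biopython does this natively), and GFF3 output converts back.  Ambiguity
codes other than N are rejected at read time: deposited nucleomorph
sequences are unambiguous and downstream translation assumes {A,C,G,T}.
Codons containing N translate to X and never match ATG or a stop.

Coding capacity partitions every base into functional protein
(plastid-associated genes included), RNA, hypothetical ORF, or intergenic.
Overlaps are merged within a class, and bases claimed by two classes are
attributed with priority functional > RNA > hypothetical; the four
percentages therefore sum to 100 exactly.  Only annotated RNA feature
spans count as RNA — spacers inside rDNA operon regions are not
separately modeled.  Features on either strand contribute identically
(strand-blind union).

## ORF calling

Six-frame, ATG-initiated, stop-terminated maximal ORFs under the standard
genetic code: an ORF starts at the first ATG after the previous in-frame
stop and ends at the next in-frame stop.  ORFs reaching a sequence end
without a stop are not reported; complete nucleomorph chromosomes end in
telomere repeats, so nothing real is lost.  The calling floor is a
parameter with default `min_aa = 50`, inclusive — inclusive floors are the
convention in ORF finders.  Overlapping ORFs on opposite strands are all
reported; selection among them is the classifier's job, which matches the
reality of gene-dense genomes.

## Pairwise similarity and classification

The largest proteome here is a few hundred sequences, so the heuristic
seeded-search machinery of database tools is unnecessary: every candidate
pair is aligned with exact Smith–Waterman (BLOSUM62, affine gaps costing
11 + k for a gap of length k; biotite's `align_optimal` with gap penalty
(−12, −1) implements exactly this convention, which we verified
numerically against a plain DP implementation).  Bitscores and e-values
use the standard gapped Karlin–Altschul constants for BLOSUM62/11/1
(λ = 0.267, K = 0.041) and the uncorrected search space m·n of the raw
sequence lengths, so thresholds are directly interpretable; the
significance threshold is e < 0.05.

A k-mer prefilter (k = 5, ≥ 8 shared words, words occurring in > 200
sequences skipped) stands in for the seeding stage.  The stringency was
chosen for the amino-acid composition these proteomes actually have:
AT-rich codon usage concentrates the residue distribution (match
probability per aligned position ≈ 0.09 rather than 0.05), so unrelated
proteins share far more exact words than a uniform model predicts.  At
≥ 8 shared 5-mers, unrelated pairs essentially never reach the alignment
stage, while homolog pairs at the divergences of interest share tens of
words.  One residual effect remains by design: a very long hypothetical
ORF can still clear e < 0.05 against some reference by chance (the
threshold is permissive, as it is with real database searches at e = 0.05);
in the full-scale simulation this promotes roughly one ORF in a few
thousand.

Classification is three-way and exhaustive: best significant reference hit
→ functional (plastid-associated when the label is on the configured
panel); otherwise any significant cross-genome hit → nORF; otherwise
nORFan.  Families are connected components of the significant-hit graph
with deterministic ids (lexicographically smallest member).  Functional
labels propagate within a family to hypothetical members
("synteny-transferred"); conflicting labels are flagged, never resolved
silently.

The gene panels shipped with the package (16-gene core plastid set, 9
photosynthesis-only genes, 19 genes shared by the colorless CCAC1634B
strain with *C. curvata*, and the combined 31-gene plastid panel) follow
the published gene lists for these strains.  Which of the
ambiguously-assignable genes (e.g. gyrA/gyrB, orf152/orf826) count as
plastid-associated is decided by the panel file, which the user can edit.

## Synteny

Anchors live in gene-order space (the index of a CDS along its
chromosome), not base-pair space: nucleomorph spacers are tiny and the
genomes align gene for gene.  Only families single-copy in both genomes
anchor; multi-copy families emit all pairings flagged ambiguous and are
used exclusively by the duplication caller, which prevents chimeric
blocks.  Blocks are extracted greedily: repeatedly take the longest
monotone chain (gap ≤ `max_gap_genes` = 3 on both genomes; ties prefer
same orientation, then leftmost), remove its anchors, stop below
`min_anchors` = 2.  The baseline chromosome correspondence is the
maximum-weight assignment on anchor counts; blocks off that matching are
inter-chromosomal calls, with the two reciprocal halves of one exchange
merged into a single call.  "Sub-telomeric" means the block span lies
within `subtelomere_bp` = 25 kb of a chromosome end in both genomes; the
window is a flag because no published number exists.

## Fragmentation, pseudogenes, telomeres

A fragmentation event is a family with exactly one member in genome A and
k ≥ 2 members in B that sit consecutively (≤ `gap_tol` = 2 intervening
genes) on one chromosome, each aligning to the intact protein, with
near-disjoint query intervals (≤ 15 aa overlap), order consistent with
gene order (reversed for minus-strand loci), and combined coverage
≥ `min_coverage` = 0.6.  Coverage substitutes for any fixed length
tolerance, since fragments "adding up to approximately the same length" is
the only observable.  Events between two hypothetical ORFs are reported as
fragmentation but never as pseudogenes; a pseudogene call requires a
functional label on the intact copy.

Disruption typing reads the junction phase from genomic coordinates
(strand-local): downstream fragment shifted by −1 nt (phase 2 mod 3)
→ frameshift_deletion; phase 0 with the upstream fragment's terminal stop
→ premature_stop; junctions whose aligned spans do not abut within 30 aa
→ undetermined.  Disruption positions are reported as the end of the
upstream fragment's aligned span on the intact protein.

Telomere decomposition scans a terminal window (default 60 bp; the right
end is reverse-complemented so both ends read outward-in) and greedily
consumes the longest maximal tandem run with motif period ≤ 3 (ties prefer
the shorter motif); positions starting no run of ≥ 2 copies are emitted
literally.  Period is capped at 3 because all observed cryptophyte
nucleomorph telomere motifs have period ≤ 3.  The invariant is expansion
identity: the decomposition always reproduces the scanned span exactly.

## The simulator

The simulator is the test bed for every stage: it produces five annotated
genomes on the fixed species topology
`((para977, paraKR), (ccac1634, (curvKR, curv979)))` with photosynthesis
lost independently on the paramecium stem and the ccac1634 branch, plus an
event log whose replay on the root genome reproduces each leaf
byte-for-byte, and a true family table.  To make replay exact, the log
records amino-acid substitutions (`divergence`) and leaf-specific ORFan
insertions (`gain`) alongside loss, fragmentation, recombination, and
duplication.

Defaults were chosen once so that leaf genomes land inside the empirically
observed ranges for *Cryptomonas* nucleomorphs and were not revisited:

- root: 570 genes = 330 functional (including 31 plastid-associated,
  labeled from the shipped panel) + 45 RNA + 195 hypothetical, on 3
  chromosomes; mean gene 300 aa (gamma, shape 3), spacers ~150 bp,
  GC target 26 %; rDNA operons at chromosome ends (reduced to a single 5S
  on chromosomes 1–2 of the paramecium strains); per-strain telomere
  literals as observed, e.g. `(GA)4GT`.
- rates per gene per unit branch length: loss 0.2; plastid-gene loss on
  colorless branches multiplied by 15 (the 16-gene core panel is exempt —
  those genes are retained in every lineage — and photosynthesis genes are
  under selection on colored branches, rate 0); fragmentation 0.1 with
  k uniform in [2, 6] as gene length allows and each fragment ≥ 52 aa;
  amino-acid divergence 0.2 substitutions/site; recombination 0.5 and
  duplication 0.2 events per genome, with recombination restricted to
  terminal segments exchanged between chromosome ends and breakpoints
  falling only in intergenic gaps; 10 ORFan gains per leaf.

No published estimates exist for these rates; they are calibration
constants of the test bed, not biological inferences.  With them, the
simulated genomes measure ~0.54–0.56 Mb, GC ≈ 26.7 %, coding capacity
≈ 86 %, ~520 protein-coding genes, and colorless leaves retain ~17–18 of
31 plastid genes while photosynthetic leaves keep all 31.

Two intentional simplifications matter for interpreting tests.  First,
gene sequences are random codon strings: the simulator reproduces the
*detectability structure* of homology (identity decaying with divergence)
but not real protein families, domain architecture, or rate variation —
passing tests show the pipeline's logic is correct, not that the e-value
threshold is optimal for real nucleomorph proteins.  Second, a spacer
boundary carries fixed in-frame stop codons on both strands, so every
intact simulated gene is exactly recoverable by the ORF caller; in real
genomes an upstream in-frame ATG without an intervening stop can extend a
called ORF beyond the annotated start.  Fragment ORFs are constructed to
be exact ATG..stop open reading frames: premature-stop junctions rewrite
two codons (stop + new ATG); frameshift junctions delete one base such
that the upstream fragment terminates immediately and the downstream
fragment continues the original codon grid in the −1 frame.  Amino-acid
divergence is i.i.d. per site with a flat kernel and is not applied to
already-fragmented loci.

Desk-scale configurations (`desk_config`: 64 genes, mean 200 aa, same
rates) are used throughout the test suite and for the multi-seed recovery
measurements in the acceptance script; full-scale runs
(`SimulationConfig()`) back the architecture statistics.  Problem sizes
were chosen so the whole suite runs in about a minute.

For the rearrangement-recovery measurements, events are *planted*
explicitly on one leaf (distinct chromosome ends per exchange,
non-overlapping duplication runs) on top of an event-free background
rather than drawn from rates: stacked random events can overwrite one
another (a segment moved twice, duplications of duplications), in which
case no caller could recover the individual events from the end state,
and the measurement would conflate detector errors with unidentifiable
histories.

## Scope

The pipeline ingests real deposited nucleomorph records (GenBank flat
files) through `nmcomp.io.read_genome` for the same analyses; network
retrieval, read-level processing (trimming/assembly/scaffolding), tRNA and
intron prediction, searches against external databases, and figure
rendering are out of scope — the package exports machine-readable tables
(links, matrices, Venn JSON) for standard plotting tools.
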
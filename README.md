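# nmcomp — comparative genomics of reduced nucleomorph genomes

Nucleomorphs are the relict nuclei of secondary algal endosymbionts,
retained between the plastid membrane pairs of cryptophyte algae.  Their
genomes are among the most reduced nuclear genomes known: three small
linear chromosomes (~0.5–0.7 Mb in total), 84–87 % coding, sub-telomeric
rDNA operons, short tandem telomere repeats, and a gene set split between
proteins of predictable function, plastid-associated genes, and a large
residue of hypothetical ORFs.  Within the genus *Cryptomonas*,
photosynthesis has been lost repeatedly, and comparing colorless against
photosynthetic strains exposes genome reduction in action: loss of
photosynthesis-related genes, ORF fragmentation, pseudogene formation, and
sub-telomeric inter-chromosomal recombination.

`nmcomp` is an analysis pipeline for exactly this kind of five-way genome
comparison, aimed at researchers studying endosymbiont genome reduction.
Every stage is a library module, and a forward simulator generates
ground-truthed synthetic nucleomorph genomes so that every stage is
testable at desk scale:

| stage | module | what it does |
|---|---|---|
| data model & I/O | `nmcomp.genome`, `nmcomp.io` | GenBank / FASTA+GFF3 genomes, 0-based half-open coordinates, GC and coding-capacity statistics |
| simulation | `nmcomp.simulate` | 5-leaf forward evolution with loss, fragmentation, recombination, duplication, divergence; byte-exact event-log replay |
| ORF calling | `nmcomp.orfs` | six-frame ATG-to-stop calling, ≥ 50 aa floor, standard genetic code |
| homology | `nmcomp.homology` | exact Smith–Waterman (BLOSUM62, affine 11/1), e-value < 0.05; functional / nORF / nORFan classification; family clustering |
| synteny | `nmcomp.synteny` | gene-order anchor chaining, inter-chromosomal / inversion / duplication calls, links export |
| degradation | `nmcomp.degradation` | 1-vs-k fragmentation detection, frameshift vs premature-stop typing, telomere repeat decomposition |
| census | `nmcomp.census` | presence/absence matrices over gene panels, shared-family Venn partition, per-genome overview table |

## The statistics at the core

**Similarity.** Instead of a heuristic database search, every candidate
protein pair (pre-screened by shared 5-mers) is aligned by exact local
Smith–Waterman with BLOSUM62 and affine gap cost 11 + k.  Raw score S is
converted with fixed gapped Karlin–Altschul constants (λ = 0.267,
K = 0.041):

    S' = (λS − ln K) / ln 2        E = m·n·2^(−S')

and a pair is a hit when E < 0.05 on the raw search space m·n.

**Classification.**  An ORF whose best significant hit is a labeled
functional reference protein is *functional* (*plastid-associated* when the
label is on the plastid panel); otherwise, any significant hit in another
nucleomorph genome makes it a conserved nucleomorph ORF (*nORF*); otherwise
it is a strain-specific *nORFan*.  Families are connected components of the
hit graph.

**Synteny.**  Anchors are single-copy shared families indexed by gene order
along chromosomes; blocks are maximal monotone anchor chains tolerating
≤ 3 unanchored intervening genes.  Rearrangements are deviations from the
maximum-weight chromosome pairing; duplications come from multi-copy
family runs.

**Degradation.**  A fragmentation event is one intact gene in genome A
matched, in syntenic position, by k ≥ 2 consecutive ORFs in genome B whose
aligned spans tile ≥ 60 % of the intact protein in order.  Junctions are
typed from genomic phase: a −1 nt shift is a single-base
(frameshift) deletion; an in-frame stop at the junction is a premature
stop.  Telomeres are decomposed greedily into tandem motifs of period ≤ 3,
e.g. `(GA)4GT`.

## Worked example

The numbered drivers under `analysis/` run the whole study on simulated
genomes (seed 1 by default; pass another seed as the first argument):

```sh
python analysis/01_simulate.py      # writes results/sim/*.gb, events, truth
python analysis/03_classify.py
python analysis/06_census.py
```

`01_simulate.py` prints the per-strain architecture:

```
para977     543,707 bp  GC 26.72%  CDS 526
paraKR      542,837 bp  GC 26.75%  CDS 518
ccac1634    539,841 bp  GC 26.72%  CDS 529
curvKR      560,663 bp  GC 26.67%  CDS 518
curv979     555,668 bp  GC 26.66%  CDS 518
```

Three strains (`para977`, `paraKR`, `ccac1634`) are colorless;
`06_census.py` shows the expected signature of photosynthesis loss — they
retain only 17–18 of the 31 plastid-associated genes that both
photosynthetic `curvata` strains keep — and reports that 150 of 192 nORF
families are shared by all five strains.  `03_classify.py` reports
per-genome category counts and that classification disagrees with the
simulator's ground truth on 1 of 2609 ORFs (a long hypothetical ORF
promoted by a chance reference hit at the permissive e < 0.05 threshold).

The same stages run from a shell on exported files via the `nmcomp` CLI
(`nmcomp simulate|annotate|classify|synteny|degradation|census --help`),
and `nmcomp.io.read_genome` ingests real deposited nucleomorph records
(GenBank flat files) for the same analyses.

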
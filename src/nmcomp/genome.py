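"""Core data model for annotated nucleomorph genomes.

Nucleomorph genomes are the residual nuclei of secondary endosymbionts:
three small linear chromosomes (~150-230 kb each), densely packed genes,
sub-telomeric rDNA operons and short tandem telomere repeats.  This module
holds the in-memory representation used by every other stage: chromosomes
with ordered, strand-aware features, per-genome composition statistics and
the four-way coding-capacity breakdown (functional protein / RNA /
hypothetical ORF / intergenic).

Coordinates are 0-based half-open throughout; format readers and writers
convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

VALID_BASES = set("ACGTN")
STRANDS = ("+", "-")
KINDS = ("CDS", "rRNA", "tRNA")
CATEGORIES = ("functional", "plastid_associated", "nORF", "nORFan", "unclassified")

#: categories whose CDS features count as "hypothetical ORFs"
HYPOTHETICAL = ("nORF", "nORFan")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeValidationError(ValueError):
    """Raised when a genome, chromosome or feature violates its invariants."""


@dataclass
class GeneFeature:
    """A located, stranded, categorized gene on one chromosome.

    ``start``/``end`` are 0-based half-open base-pair coordinates on the
    forward strand of the chromosome.  ``category`` stays ``unclassified``
    until homology classification assigns it; ``family_id`` carries either
    simulator ground truth or the id assigned by family clustering.
    """

    feature_id: str
    chromosome_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    category: str = "unclassified"
    product: str | None = None
    protein: str | None = None
    family_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeValidationError(
                f"feature {self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise GenomeValidationError(f"feature {self.feature_id}: bad strand {self.strand!r}")
        if self.kind not in KINDS:
            raise GenomeValidationError(f"feature {self.feature_id}: bad kind {self.kind!r}")
        if self.category not in CATEGORIES:
            raise GenomeValidationError(
                f"feature {self.feature_id}: bad category {self.category!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def copy(self, **changes) -> "GeneFeature":
        return replace(self, **changes)


@dataclass
class Chromosome:
    """One linear nucleomorph chromosome: sequence plus ordered features."""

    id: str
    seq: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise GenomeValidationError(
                f"chromosome {self.id}: ambiguity codes other than N are not "
                f"supported (found {sorted(bad)})"
            )
        self.features.sort(key=lambda f: (f.start, f.end, f.feature_id))
        for f in self.features:
            if f.end > len(self.seq):
                raise GenomeValidationError(
                    f"feature {f.feature_id} extends past end of chromosome {self.id} "
                    f"({f.end} > {len(self.seq)})"
                )

    @property
    def length(self) -> int:
        return len(self.seq)

    def feature_seq(self, feature: GeneFeature) -> str:
        s = self.seq[feature.start:feature.end]
        return s if feature.strand == "+" else revcomp(s)


@dataclass
class Genome:
    """A strain's annotated genome: an ordered set of chromosomes."""

    strain_id: str
    chromosomes: list[Chromosome]
    photosynthetic: bool = True

    @property
    def size(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def get_chromosome(self, chrom_id: str) -> Chromosome:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise KeyError(chrom_id)

    def iter_features(self):
        for c in self.chromosomes:
            yield from c.features

    def cds_features(self) -> list[GeneFeature]:
        return [f for f in self.iter_features() if f.kind == "CDS"]

    def cds_order(self) -> dict[str, tuple[str, int, str]]:
        """Map feature_id -> (chromosome_id, gene index along chromosome, strand).

        Gene indices count CDS features only, in start-coordinate order; this
        is the order space in which synteny anchors live.
        """
        order: dict[str, tuple[str, int, str]] = {}
        for c in self.chromosomes:
            cds = [f for f in c.features if f.kind == "CDS"]
            for i, f in enumerate(cds):
                order[f.feature_id] = (c.id, i, f.strand)
        return order


@dataclass
class GCStat:
    genome_id: str
    gc_percent: float


def gc_percent(seqs) -> float:
    """G+C percentage over one or more sequences; N excluded from the denominator."""
    if isinstance(seqs, str):
        seqs = [seqs]
    gc = 0
    atgc = 0
    for s in seqs:
        gc += s.count("G") + s.count("C")
        atgc += len(s) - s.count("N")
    if atgc == 0:
        raise GenomeValidationError("cannot compute GC of an empty/all-N sequence")
    return 100.0 * gc / atgc


def genome_stats(g: Genome) -> dict:
    """Per-genome summary: size, GC, feature counts by kind, chromosome sizes."""
    if not g.chromosomes or g.size == 0:
        raise GenomeValidationError(f"genome {g.strain_id} is empty")
    counts = {k: 0 for k in KINDS}
    for f in g.iter_features():
        counts[f.kind] += 1
    return {
        "genome_id": g.strain_id,
        "size_bp": g.size,
        "chromosome_sizes": [c.length for c in g.chromosomes],
        "n_chromosomes": len(g.chromosomes),
        "gc": GCStat(g.strain_id, gc_percent([c.seq for c in g.chromosomes])),
        "n_features_by_kind": counts,
    }


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(intervals: list[tuple[int, int]], mask: list[tuple[int, int]]):
    """Subtract a merged mask from merged intervals (both sorted, disjoint)."""
    out = []
    for s, e in intervals:
        cur = s
        for ms, me in mask:
            if me <= cur:
                continue
            if ms >= e:
                break
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def _covered(intervals) -> int:
    return sum(e - s for s, e in intervals)


def coding_capacity(g: Genome) -> dict:
    """Four-way coding-capacity breakdown in percent of genome length.

    Bases covered by annotated features are attributed with priority
    functional (incl. plastid-associated) > RNA > hypothetical ORF, overlaps
    merged within each class and the remainder counted as intergenic.  CDS
    features must already be classified.
    """
    if g.size == 0:
        raise GenomeValidationError(f"genome {g.strain_id} is empty")
    fun = rna = hyp = 0
    for c in g.chromosomes:
        fun_iv, rna_iv, hyp_iv = [], [], []
        for f in c.features:
            if f.kind in ("rRNA", "tRNA"):
                rna_iv.append((f.start, f.end))
            elif f.category in ("functional", "plastid_associated"):
                fun_iv.append((f.start, f.end))
            elif f.category in HYPOTHETICAL:
                hyp_iv.append((f.start, f.end))
            else:
                raise GenomeValidationError(
                    f"CDS feature {f.feature_id} is unclassified; run homology "
                    "classification before computing coding capacity"
                )
        fun_iv = _merge(fun_iv)
        rna_iv = _subtract(_merge(rna_iv), fun_iv)
        mask = _merge(fun_iv + rna_iv)
        hyp_iv = _subtract(_merge(hyp_iv), mask)
        fun += _covered(fun_iv)
        rna += _covered(rna_iv)
        hyp += _covered(hyp_iv)
    total = g.size
    pct = {
        "functional_pct": 100.0 * fun / total,
        "rna_pct": 100.0 * rna / total,
        "hypothetical_pct": 100.0 * hyp / total,
    }
    pct["intergenic_pct"] = 100.0 - sum(pct.values())
    return pct
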
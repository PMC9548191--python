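"""Genome-reduction readouts: ORF fragmentation, pseudogene typing, telomeres.

A fragmentation event is the syntenic configuration in which one intact
gene in genome A corresponds to k >= 2 consecutive smaller ORFs in genome
B, each aligning to a distinct, essentially non-overlapping span of the
intact protein, in the same order.  When the intact copy carries a
functional label the event is a pseudogene candidate, and the disrupting
mutations are typed from the genomic sequence at the fragment junctions:
a net single-base deletion that shifts the downstream reading frame is a
frameshift_deletion; an in-frame junction behind a stop codon is a
premature_stop.

Telomere decomposition represents a chromosome end as an ordered list of
tandem motifs with copy numbers, e.g. (GA)4GT, scanning outward-in with
motif periods up to 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import Chromosome, Genome, revcomp
from .homology import GeneFamily, HomologyHit, align_proteins


@dataclass
class FragmentationEvent:
    intact_genome: str
    intact_feature_id: str
    fragmented_genome: str
    fragment_ids: list[str]
    combined_coverage: float
    order_consistent: bool
    family_id: str | None = None
    hits: list[HomologyHit] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.fragment_ids)


@dataclass
class PseudogeneCall:
    event: FragmentationEvent
    functional_label: str
    disruption_type: str                 # frameshift_deletion | premature_stop | undetermined
    disruption_positions: list[int] = field(default_factory=list)  # aa on intact protein


@dataclass
class TelomereModel:
    chromosome_id: str
    chromosome_end: str                  # left | right
    decomposition: list[tuple[str, int]]
    literal: str
    span: str                            # terminal sequence read outward-in

    def expand(self) -> str:
        return "".join(motif * copies for motif, copies in self.decomposition)


def detect_fragmentation(families: list[GeneFamily],
                         genomes: dict[str, Genome],
                         proteins: dict[str, dict[str, str]],
                         min_coverage: float = 0.6,
                         gap_tol: int = 2,
                         evalue_max: float = 0.05,
                         blocks=None,
                         overlap_tol_aa: int = 15) -> list[FragmentationEvent]:
    """Scan families for 1-vs-k syntenic configurations between genome pairs.

    proteins: genome_id -> {feature_id -> aa}.  For every ordered genome
    pair (A, B) and every family with exactly one member in A and k >= 2
    members in B lying consecutively (<= gap_tol intervening genes) on one
    chromosome, the B proteins are aligned to the intact A protein; the
    event is emitted when the aligned query intervals are (near-)disjoint,
    ordered consistently with gene order, and jointly cover at least
    min_coverage of the intact protein.
    """
    orders = {gid: g.cds_order() for gid, g in genomes.items()}
    events: list[FragmentationEvent] = []
    for fam in sorted(families, key=lambda f: f.family_id):
        by_genome: dict[str, list[str]] = {}
        for g, f in fam.members:
            by_genome.setdefault(g, []).append(f)
        for ga, mem_a in sorted(by_genome.items()):
            if len(mem_a) != 1 or mem_a[0] not in proteins.get(ga, {}):
                continue
            intact = mem_a[0]
            intact_aa = proteins[ga][intact]
            for gb, mem_b in sorted(by_genome.items()):
                if gb == ga or len(mem_b) < 2:
                    continue
                ev = _check_candidate(
                    ga, intact, intact_aa, gb, mem_b, orders[gb],
                    proteins[gb], min_coverage, gap_tol, evalue_max,
                    overlap_tol_aa)
                if ev is not None:
                    ev.family_id = fam.family_id
                    events.append(ev)
    return events


def _check_candidate(ga, intact, intact_aa, gb, mem_b, order_b, prot_b,
                     min_coverage, gap_tol, evalue_max, overlap_tol):
    pos = [(order_b[m], m) for m in mem_b if m in order_b and m in prot_b]
    if len(pos) < 2:
        return None
    chroms = {p[0] for p, _ in pos}
    if len(chroms) != 1:
        return None
    pos.sort(key=lambda x: x[0][1])
    idxs = [p[1] for p, _ in pos]
    if any(b - a > gap_tol + 1 for a, b in zip(idxs, idxs[1:])):
        return None
    strand = pos[0][0][2]
    if strand == "-":          # fragments of a minus-strand gene run C->N left to right
        pos = pos[::-1]
    hits = []
    for (_, m) in pos:
        h = align_proteins(intact_aa, prot_b[m], intact, m, evalue_max)
        if h is None:
            return None
        hits.append(h)
    starts = [h.q_interval[0] for h in hits]
    order_consistent = all(b > a for a, b in zip(starts, starts[1:]))
    disjoint = all(h2.q_interval[0] >= h1.q_interval[1] - overlap_tol
                   for h1, h2 in zip(hits, hits[1:]))
    covered: set[int] = set()
    for h in hits:
        covered.update(range(*h.q_interval))
    coverage = len(covered) / len(intact_aa)
    if not (order_consistent and disjoint and coverage >= min_coverage):
        return None
    return FragmentationEvent(
        intact_genome=ga, intact_feature_id=intact, fragmented_genome=gb,
        fragment_ids=[m for _, m in pos], combined_coverage=coverage,
        order_consistent=order_consistent, hits=hits,
    )


def type_disruption(event: FragmentationEvent,
                    genomes: dict[str, Genome],
                    functional_label: str,
                    max_boundary_gap_aa: int = 30) -> PseudogeneCall:
    """Type the disrupting mutations of a pseudogene candidate.

    For each junction between consecutive fragments the phase offset of the
    downstream fragment relative to the upstream one is read from genomic
    coordinates (strand-local): a phase shift of -1 nt is the signature of a
    single-base deletion restoring frame in the annotation
    (frameshift_deletion); phase 0 with the upstream fragment's terminal
    stop codon intact is a premature_stop.  Junctions whose aligned spans on
    the intact protein do not abut are left undetermined.
    """
    gb = genomes.get(event.fragmented_genome)
    if gb is None:
        raise ValueError(f"no genomic sequence for {event.fragmented_genome}")
    featmap = {f.feature_id: (c, f) for c in gb.chromosomes for f in c.features}
    frags = []
    for fid in event.fragment_ids:
        if fid not in featmap:
            raise ValueError(f"fragment {fid} not found in {event.fragmented_genome}")
        frags.append(featmap[fid])
    hits = {h.subject_id: h for h in event.hits}
    types = []
    positions = []
    for (c1, f1), (c2, f2) in zip(frags, frags[1:]):
        h1, h2 = hits.get(f1.feature_id), hits.get(f2.feature_id)
        if h1 is None or h2 is None or c1.id != c2.id or f1.strand != f2.strand:
            types.append("undetermined")
            continue
        gap_aa = h2.q_interval[0] - h1.q_interval[1]
        if not (-max_boundary_gap_aa <= gap_aa <= max_boundary_gap_aa):
            types.append("undetermined")
            continue
        if f1.strand == "+":
            phase = (f2.start - f1.start) % 3
            stop = c1.seq[f1.end - 3:f1.end]
        else:
            phase = (f1.end - f2.end) % 3
            stop = revcomp(c1.seq[f1.start:f1.start + 3])
        if phase == 2:
            types.append("frameshift_deletion")
        elif phase == 0 and stop in ("TAA", "TAG", "TGA"):
            types.append("premature_stop")
        else:
            types.append("undetermined")
        positions.append(h1.q_interval[1])
    if not types:
        dtype = "undetermined"
    elif len(set(types)) == 1:
        dtype = types[0]
    else:
        determined = [t for t in types if t != "undetermined"]
        dtype = determined[0] if len(set(determined)) == 1 else "undetermined"
    return PseudogeneCall(event=event, functional_label=functional_label,
                          disruption_type=dtype, disruption_positions=positions)


def decompose_telomere(chrom: Chromosome, end: str, window: int = 60) -> TelomereModel:
    """Greedy tandem-repeat decomposition of a terminal window, outward-in.

    The right end is read as the reverse complement so both models read from
    the chromosome terminus inward.  At each position the longest maximal
    tandem run with motif period 1-3 is consumed (ties prefer the shorter
    motif); positions starting no run of >= 2 copies are emitted literally.
    """
    if end not in ("left", "right"):
        raise ValueError("end must be 'left' or 'right'")
    window = min(window, chrom.length)
    if end == "left":
        span = chrom.seq[:window]
    else:
        span = revcomp(chrom.seq[-window:])
    if set(span) <= {"N"}:
        raise ValueError(f"terminal window of {chrom.id} ({end}) is all N")
    decomposition = decompose_repeats(span)
    literal = render_literal(decomposition)
    return TelomereModel(chrom.id, end, decomposition, literal, span)


def decompose_repeats(s: str, max_period: int = 3) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    i = 0
    n = len(s)
    while i < n:
        best = None  # (span, -period, motif, copies)
        for p in range(1, max_period + 1):
            if i + 2 * p > n:
                break
            motif = s[i:i + p]
            copies = 1
            while s[i + copies * p: i + (copies + 1) * p] == motif:
                copies += 1
            if copies >= 2:
                cand = (p * copies, -p, motif, copies)
                if best is None or cand > best:
                    best = cand
        if best is None:
            if out and out[-1][1] == 1:
                out[-1] = (out[-1][0] + s[i], 1)
            else:
                out.append((s[i], 1))
            i += 1
        else:
            _, _, motif, copies = best
            out.append((motif, copies))
            i += len(motif) * copies
    return out


def render_literal(decomposition: list[tuple[str, int]]) -> str:
    return "".join(f"({m}){c}" if c >= 2 else m for m, c in decomposition)


def genome_telomeres(g: Genome, window: int = 60) -> list[TelomereModel]:
    out = []
    for c in g.chromosomes:
        for end in ("left", "right"):
            out.append(decompose_telomere(c, end, window))
    return out
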
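"""Synteny-block detection and rearrangement calling between genome pairs.

Anchors live in gene-order space (index of a CDS along its chromosome), not
base-pair space: nucleomorph intergenic spacers are tiny and the genomes
align gene for gene.  Single-copy shared families give one anchor each;
multi-copy families emit all pairings flagged ambiguous and are handled
only by the duplication caller, never chained.

Blocks are maximal monotone anchor chains tolerating a bounded number of
unanchored intervening genes on either genome.  The baseline chromosome
correspondence is the maximum-weight matching on anchors per chromosome
pair; blocks that deviate from it are inter-chromosomal rearrangement
calls, flagged sub-telomeric when they lie within a terminal window on
both genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genome import Genome


@dataclass(frozen=True)
class AnchorSide:
    chromosome_id: str
    index: int          # gene index along chromosome (CDS order space)
    strand: str
    start: int          # bp
    end: int


@dataclass(frozen=True)
class Anchor:
    family_id: str
    a: AnchorSide
    b: AnchorSide
    ambiguous: bool = False


@dataclass
class SyntenyBlock:
    block_id: str
    genome_a: str
    genome_b: str
    anchors: list[Anchor]
    orientation: str            # "same" | "inverted"

    @property
    def chrom_a(self) -> str:
        return self.anchors[0].a.chromosome_id

    @property
    def chrom_b(self) -> str:
        return self.anchors[0].b.chromosome_id

    @property
    def span_a(self) -> tuple[int, int]:
        return (min(x.a.start for x in self.anchors),
                max(x.a.end for x in self.anchors))

    @property
    def span_b(self) -> tuple[int, int]:
        return (min(x.b.start for x in self.anchors),
                max(x.b.end for x in self.anchors))

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class RearrangementCall:
    type: str                     # inter_chromosomal | inversion | duplication
    blocks: list[SyntenyBlock] = field(default_factory=list)
    families: list[str] = field(default_factory=list)
    chromosomes: tuple = ()
    sub_telomeric: bool = False


def build_anchors(families, ga: Genome, gb: Genome) -> list[Anchor]:
    """One anchor per family single-copy in both genomes; multi-copy
    families emit all pairings flagged ambiguous."""
    pos_a = _positions(ga)
    pos_b = _positions(gb)
    anchors: list[Anchor] = []
    for fam in sorted(families, key=lambda f: f.family_id):
        mem_a = sorted(f for g, f in fam.members if g == ga.strain_id)
        mem_b = sorted(f for g, f in fam.members if g == gb.strain_id)
        mem_a = [m for m in mem_a if m in pos_a]
        mem_b = [m for m in mem_b if m in pos_b]
        if not mem_a or not mem_b:
            continue
        ambiguous = len(mem_a) > 1 or len(mem_b) > 1
        for ma in mem_a:
            for mb in mem_b:
                anchors.append(Anchor(fam.family_id, pos_a[ma], pos_b[mb], ambiguous))
    return anchors


def _positions(g: Genome) -> dict[str, AnchorSide]:
    out = {}
    for c in g.chromosomes:
        cds = [f for f in c.features if f.kind == "CDS"]
        for i, f in enumerate(cds):
            out[f.feature_id] = AnchorSide(c.id, i, f.strand, f.start, f.end)
    return out


def _best_chain(items, max_gap: int, direction: int):
    """Longest monotone chain under the gap constraint; items sorted by a-index.

    direction +1: b-index increasing; -1: decreasing.  Returns list of item
    indices.  Ties break toward the leftmost start.
    """
    n = len(items)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        ai, bi = items[i]
        for j in range(i):
            aj, bj = items[j]
            da = ai - aj
            db = (bi - bj) * direction
            if 0 < da <= max_gap + 1 and 0 < db <= max_gap + 1:
                if best_len[j] + 1 > best_len[i]:
                    best_len[i] = best_len[j] + 1
                    prev[i] = j
    if n == 0:
        return []
    end = max(range(n), key=lambda i: (best_len[i], -items[i][0]))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def chain_blocks(anchors: list[Anchor], max_gap_genes: int = 3,
                 min_anchors: int = 2, genome_a: str = "a",
                 genome_b: str = "b") -> list[SyntenyBlock]:
    """Greedy extraction of maximal monotone anchor chains.

    Repeatedly takes the longest remaining chain (same orientation preferred
    on ties, then leftmost), removes its anchors, until no chain reaches
    min_anchors.  Ambiguous anchors are excluded.
    """
    pool: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        if a.ambiguous:
            continue
        pool.setdefault((a.a.chromosome_id, a.b.chromosome_id), []).append(a)
    blocks: list[SyntenyBlock] = []
    counter = 0
    for key in sorted(pool):
        group = sorted(pool[key], key=lambda x: (x.a.index, x.b.index))
        active = list(range(len(group)))
        while True:
            items = [(group[i].a.index, group[i].b.index) for i in active]
            cand = []
            for direction, orient in ((1, "same"), (-1, "inverted")):
                chain = _best_chain(items, max_gap_genes, direction)
                if chain:
                    cand.append((len(chain), orient == "same",
                                 -items[chain[0]][0], chain, orient))
            if not cand:
                break
            cand.sort(reverse=True)
            size, _, _, chain, orient = cand[0]
            if size < min_anchors:
                break
            sel = [active[i] for i in chain]
            blocks.append(SyntenyBlock(
                block_id=f"blk{counter:04d}",
                genome_a=genome_a, genome_b=genome_b,
                anchors=[group[i] for i in sel],
                orientation=orient,
            ))
            counter += 1
            used = set(sel)
            active = [i for i in active if i not in used]
    blocks.sort(key=lambda b: (b.chrom_a, b.span_a))
    for i, b in enumerate(blocks):
        b.block_id = f"blk{i:04d}"
    return blocks


def _chrom_matching(blocks) -> dict[str, str]:
    """Baseline chromosome pairing: maximum-weight matching on anchor totals."""
    ca = sorted({b.chrom_a for b in blocks})
    cb = sorted({b.chrom_b for b in blocks})
    w = np.zeros((len(ca), len(cb)))
    for b in blocks:
        w[ca.index(b.chrom_a), cb.index(b.chrom_b)] += b.n_anchors
    rows, cols = linear_sum_assignment(-w)
    return {ca[i]: cb[j] for i, j in zip(rows, cols) if w[i, j] > 0}


def _near_end(span: tuple[int, int], chrom_len: int, window: int) -> bool:
    return span[1] <= window or span[0] >= chrom_len - window


def call_rearrangements(blocks: list[SyntenyBlock], anchors: list[Anchor],
                        ga: Genome, gb: Genome,
                        subtelomere_bp: int = 25000) -> list[RearrangementCall]:
    """Inter-chromosomal, inversion, and duplication calls from blocks.

    Inter-chromosomal: blocks pairing chromosomes off the baseline matching;
    reciprocal partners (the two halves of one exchange) are merged into a
    single call.  Duplication: runs of multi-copy (ambiguous) families with
    two consecutive copy tracts in one genome.
    """
    calls: list[RearrangementCall] = []
    if blocks:
        matching = _chrom_matching(blocks)
        inv_matching = {v: k for k, v in matching.items()}
        off: dict[frozenset, list[SyntenyBlock]] = {}
        for b in blocks:
            if matching.get(b.chrom_a) == b.chrom_b:
                if b.orientation == "inverted":
                    calls.append(RearrangementCall(
                        type="inversion", blocks=[b],
                        families=[a.family_id for a in b.anchors],
                        chromosomes=(b.chrom_a, b.chrom_b),
                        sub_telomeric=_sub_telomeric(b, ga, gb, subtelomere_bp),
                    ))
                continue
            key = frozenset({b.chrom_a, inv_matching.get(b.chrom_b, b.chrom_b)})
            off.setdefault(key, []).append(b)
        for key in sorted(off, key=sorted):
            group = off[key]
            calls.append(RearrangementCall(
                type="inter_chromosomal",
                blocks=group,
                families=sorted({a.family_id for b in group for a in b.anchors}),
                chromosomes=tuple(sorted({c for b in group
                                          for c in (b.chrom_a, b.chrom_b)})),
                sub_telomeric=all(_sub_telomeric(b, ga, gb, subtelomere_bp)
                                  for b in group),
            ))
    calls.extend(_duplication_calls(anchors))
    return calls


def _sub_telomeric(b: SyntenyBlock, ga: Genome, gb: Genome, window: int) -> bool:
    la = ga.get_chromosome(b.chrom_a).length
    lb = gb.get_chromosome(b.chrom_b).length
    return _near_end(b.span_a, la, window) and _near_end(b.span_b, lb, window)


def _duplication_calls(anchors: list[Anchor]) -> list[RearrangementCall]:
    # families with two copies on one side form runs at two distinct loci
    by_fam: dict[str, list[Anchor]] = {}
    for a in anchors:
        if a.ambiguous:
            by_fam.setdefault(a.family_id, []).append(a)
    dup_pos: dict[tuple[str, int], str] = {}
    for fam, group in by_fam.items():
        for side in ("a", "b"):
            sides = {getattr(x, side) for x in group}
            if len(sides) > 1:
                for s in sides:
                    dup_pos[(f"{side}:{s.chromosome_id}", s.index)] = fam
    if not dup_pos:
        return []
    # group duplicated gene positions into consecutive runs per chromosome
    runs: list[tuple[str, list[str]]] = []
    for chrom in sorted({c for c, _ in dup_pos}):
        idxs = sorted(i for c, i in dup_pos if c == chrom)
        cur: list[int] = []
        for i in idxs:
            if cur and i - cur[-1] > 1:
                runs.append((chrom, [dup_pos[(chrom, j)] for j in cur]))
                cur = []
            cur.append(i)
        if cur:
            runs.append((chrom, [dup_pos[(chrom, j)] for j in cur]))
    # one call per distinct family set that occurs as >= 2 runs
    seen: dict[frozenset, list[tuple[str, list[str]]]] = {}
    for chrom, fams in runs:
        seen.setdefault(frozenset(fams), []).append((chrom, fams))
    calls = []
    for fams in sorted(seen, key=sorted):
        if len(seen[fams]) >= 2:
            calls.append(RearrangementCall(
                type="duplication",
                families=sorted(fams),
                chromosomes=tuple(sorted({c for c, _ in seen[fams]})),
            ))
    return calls


def export_links(blocks: list[SyntenyBlock], path) -> None:
    """TSV of block spans, consumable by circular-plot tools."""
    cols = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
            "orientation"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for b in blocks:
            sa, ea = b.span_a
            sb, eb = b.span_b
            fh.write("\t".join(str(v) for v in
                               [b.chrom_a, sa, ea, b.chrom_b, sb, eb,
                                b.orientation]) + "\n")
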
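"""Anchor building, block chaining vs exhaustive oracle, rearrangement calls."""

from itertools import combinations

import numpy as np
import pytest

from nmcomp.genome import Chromosome, GeneFeature, Genome
from nmcomp.homology import GeneFamily
from nmcomp.simulate import Event, apply_extra_events
from nmcomp.synteny import (Anchor, AnchorSide, build_anchors,
                            call_rearrangements, chain_blocks, export_links)


def _toy_genome(strain, orders):
    """orders: {chrom: [(feature_id, strand), ...]}; genes 100 bp apart."""
    chroms = []
    for cid, feats in orders.items():
        fs = [GeneFeature(fid, cid, 100 + 200 * i, 200 + 200 * i, strand,
                          category="nORF")
              for i, (fid, strand) in enumerate(feats)]
        chroms.append(Chromosome(cid, "A" * (300 + 200 * len(feats)), fs))
    return Genome(strain, chroms)


def _fams(pairs):
    return [GeneFamily(f"fam{i}", set(m)) for i, m in enumerate(pairs)]


def test_identical_gene_order_yields_one_block_per_chromosome(quiet_sim):
    a, b = quiet_sim.genomes["para977"], quiet_sim.genomes["curv979"]
    anchors = build_anchors(quiet_sim.families, a, b)
    blocks = chain_blocks(anchors)
    per_chrom = {}
    for blk in blocks:
        per_chrom.setdefault(blk.chrom_a, []).append(blk)
    for cid, blks in per_chrom.items():
        assert len(blks) == 1
        assert blks[0].orientation == "same"
    n_unamb = sum(1 for x in anchors if not x.ambiguous)
    assert sum(b_.n_anchors for b_ in blocks) == n_unamb


def test_chain_blocks_symmetric_under_genome_swap(desk_sim):
    a, b = desk_sim.genomes["paraKR"], desk_sim.genomes["ccac1634"]
    anchors_ab = build_anchors(desk_sim.families, a, b)
    anchors_ba = build_anchors(desk_sim.families, b, a)
    blocks_ab = chain_blocks(anchors_ab)
    blocks_ba = chain_blocks(anchors_ba)
    sig_ab = sorted(tuple(sorted((x.family_id for x in blk.anchors)))
                    for blk in blocks_ab)
    sig_ba = sorted(tuple(sorted((x.family_id for x in blk.anchors)))
                    for blk in blocks_ba)
    assert sig_ab == sig_ba


def test_family_absent_from_one_genome_gives_no_anchor():
    a = _toy_genome("A", {"c1": [("x", "+"), ("y", "+")]})
    b = _toy_genome("B", {"c1": [("x2", "+")]})
    fams = _fams([[("A", "x"), ("B", "x2")], [("A", "y")]])
    anchors = build_anchors(fams, a, b)
    assert [x.family_id for x in anchors] == ["fam0"]


def test_duplicated_family_emits_flagged_pairings():
    a = _toy_genome("A", {"c1": [("x", "+")]})
    b = _toy_genome("B", {"c1": [("x1", "+"), ("x2", "+")]})
    fams = _fams([[("A", "x"), ("B", "x1"), ("B", "x2")]])
    anchors = build_anchors(fams, a, b)
    assert len(anchors) == 2 and all(x.ambiguous for x in anchors)


def _mk_anchors(pairs_ab):
    """pairs_ab: list of (idx_a, idx_b) on one chromosome pair."""
    return [Anchor(f"f{i}", AnchorSide("c1", ia, "+", 100 * ia, 100 * ia + 50),
                   AnchorSide("c1", ib, "+", 100 * ib, 100 * ib + 50))
            for i, (ia, ib) in enumerate(pairs_ab)]


def _oracle_best_chain(pairs, max_gap):
    """Exhaustive search for the largest valid monotone chain (n <= 12)."""
    best = 0
    idx = list(range(len(pairs)))
    for r in range(1, len(pairs) + 1):
        for sub in combinations(idx, r):
            pa = [pairs[i][0] for i in sub]
            pb = [pairs[i][1] for i in sub]
            if sorted(pa) != pa:
                continue
            for direction in (1, -1):
                ok = all(0 < pa[j + 1] - pa[j] <= max_gap + 1 and
                         0 < (pb[j + 1] - pb[j]) * direction <= max_gap + 1
                         for j in range(len(sub) - 1))
                if ok:
                    best = max(best, r)
    return best


@pytest.mark.parametrize("seed", range(6))
def test_longest_block_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 10
    perm = rng.permutation(n)
    pairs = sorted((int(i), int(j)) for i, j in enumerate(perm))
    anchors = _mk_anchors(pairs)
    blocks = chain_blocks(anchors, max_gap_genes=1, min_anchors=2)
    got = max((b.n_anchors for b in blocks), default=0)
    want = _oracle_best_chain(pairs, 1)
    assert got == (want if want >= 2 else 0)


def test_planted_inversion_detected_with_inverted_orientation():
    # genome B carries genes 3..6 in reversed order/strand
    order_a = [(f"g{i}", "+") for i in range(10)]
    order_b = order_a[:3] + [(f, "-") for f, _ in reversed(order_a[3:7])] + order_a[7:]
    a = _toy_genome("A", {"c1": order_a})
    b = _toy_genome("B", {"c1": order_b})
    fams = _fams([[("A", f"g{i}"), ("B", f"g{i}")] for i in range(10)])
    blocks = chain_blocks(build_anchors(fams, a, b), max_gap_genes=1)
    inverted = [blk for blk in blocks if blk.orientation == "inverted"]
    assert len(inverted) == 1
    assert sorted(x.a.index for x in inverted[0].anchors) == [3, 4, 5, 6]
    calls = call_rearrangements(blocks, [], a, b, subtelomere_bp=0)
    assert [c.type for c in calls] == ["inversion"]


def test_planted_subtelomeric_translocation_called(quiet_sim):
    ev = Event("curv979", "recombination",
               {"end_a": ("chr1", "left"), "end_b": ("chr3", "left"),
                "n_a": 8, "n_b": 3})
    genomes, _, families = apply_extra_events(quiet_sim, "curv979", [ev])
    a, b = genomes["para977"], genomes["curv979"]
    anchors = build_anchors(families, a, b)
    blocks = chain_blocks(anchors)
    calls = call_rearrangements(blocks, anchors, a, b)
    inter = [c for c in calls if c.type == "inter_chromosomal"]
    assert len(inter) == 1
    assert inter[0].chromosomes == ("chr1", "chr3")
    assert inter[0].sub_telomeric
    moved = {blk.chrom_a for blk in inter[0].blocks} | \
            {blk.chrom_b for blk in inter[0].blocks}
    assert moved == {"chr1", "chr3"}


def test_no_rearrangements_no_calls(quiet_sim):
    a, b = quiet_sim.genomes["paraKR"], quiet_sim.genomes["curvKR"]
    anchors = build_anchors(quiet_sim.families, a, b)
    blocks = chain_blocks(anchors)
    assert call_rearrangements(blocks, anchors, a, b) == []


def test_coverage_monotone_in_gap_tolerance():
    rng = np.random.default_rng(4)
    perm = rng.permutation(20)
    pairs = sorted((int(i), int(j)) for i, j in enumerate(perm))
    anchors = _mk_anchors(pairs)
    prev = -1
    for gap in range(5):
        blocks = chain_blocks(anchors, max_gap_genes=gap)
        total = sum(b.n_anchors for b in blocks)
        assert total >= prev
        prev = total


def test_export_links(tmp_path):
    a = _toy_genome("A", {"c1": [("x", "+"), ("y", "+")]})
    b = _toy_genome("B", {"c2": [("x2", "+"), ("y2", "+")]})
    fams = _fams([[("A", "x"), ("B", "x2")], [("A", "y"), ("B", "y2")]])
    blocks = chain_blocks(build_anchors(fams, a, b))
    path = tmp_path / "links.tsv"
    export_links(blocks, path)
    lines = path.read_text().splitlines()
    assert len(lines) == 1 + len(blocks) == 2
    assert lines[1].split("\t")[0] == "c1"
    export_links([], path)
    assert path.read_text().splitlines() == [lines[0]]
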
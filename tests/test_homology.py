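"""Alignment scores vs an independent DP oracle; classification recovery."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from nmcomp.homology import (GeneFamily, align_proteins, build_families,
                             classify_orfs, evalue, shared_kmer_pairs,
                             synteny_transfer_labels)
from nmcomp.homology import ClassificationResult
from nmcomp.pipeline import classify_genomes
from nmcomp.simulate import desk_config, simulate

BLOSUM62 = substitution_matrices.load("BLOSUM62")

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _sw_oracle(q, s, gap_open=11, gap_extend=1):
    """Plain-Python affine-gap Smith-Waterman (BLAST convention: a gap of
    length l costs open + l*extend)."""
    n, m = len(q), len(s)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in s (query consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = BLOSUM62[q[i - 1], s[j - 1]]
            M[i][j] = max(0.0, max(M[i - 1][j - 1], X[i - 1][j - 1],
                                   Y[i - 1][j - 1]) + sub)
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                          X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                          Y[i][j - 1] - gap_extend)
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def _random_protein(rng, n):
    return "".join(rng.choice(list(AAS), size=n))


def _mutated(rng, p, rate=0.2, dele=0):
    out = [a if rng.random() > rate else rng.choice(list(AAS)) for a in p]
    for _ in range(dele):
        out.pop(rng.integers(0, len(out)))
    return "".join(out)


def test_identical_sequences_score_sum_of_diagonal():
    rng = np.random.default_rng(0)
    p = _random_protein(rng, 100)
    h = align_proteins(p, p)
    assert h is not None
    assert h.raw_score == sum(BLOSUM62[a, a] for a in p)
    assert h.evalue < 1e-30
    assert h.pct_identity == pytest.approx(100.0)
    assert h.q_interval == (0, 100) and h.s_interval == (0, 100)


def test_all_negative_scores_give_no_hit():
    assert align_proteins("AAAA", "WWWW") is None


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align_proteins("", "MKV")


@pytest.mark.parametrize("seed", range(6))
def test_alignment_score_matches_dp_oracle(seed):
    rng = np.random.default_rng(seed)
    p = _random_protein(rng, 60)
    q = _mutated(rng, p, rate=0.25, dele=seed % 3)
    h = align_proteins(p, q, evalue_max=1e9)
    assert h is not None
    assert h.raw_score == pytest.approx(_sw_oracle(p, q))


def test_score_symmetry():
    rng = np.random.default_rng(7)
    p = _random_protein(rng, 80)
    q = _mutated(rng, p, rate=0.3, dele=2)
    assert align_proteins(p, q, evalue_max=1e9).raw_score == \
        align_proteins(q, p, evalue_max=1e9).raw_score


def test_divergent_homologs_found_then_lost():
    """A pair at ~30% divergence is a significant hit; a pair of unrelated
    random proteins is not."""
    rng = np.random.default_rng(1)
    p = _random_protein(rng, 200)
    near = _mutated(rng, p, rate=0.3)
    far = _random_protein(rng, 200)
    assert align_proteins(p, near) is not None
    assert align_proteins(p, far) is None


def test_evalue_monotone_decreasing_in_score():
    e1 = evalue(50, 300, 300)
    e2 = evalue(80, 300, 300)
    assert e2 < e1


def test_kmer_prefilter_passes_homologs_blocks_random():
    rng = np.random.default_rng(2)
    prots = {}
    p = _random_protein(rng, 150)
    prots["a"] = p
    prots["b"] = _mutated(rng, p, rate=0.2)
    prots["c"] = _random_protein(rng, 150)
    pairs = shared_kmer_pairs(prots)
    assert ("a", "b") in pairs
    assert not any("c" in pr for pr in pairs)


def test_families_are_transitive_components():
    class H:
        def __init__(self, q, s):
            self.query_id, self.subject_id = q, s

    fams = build_families([H("g1|A", "g2|B"), H("g2|B", "g3|C")])
    assert len(fams) == 1
    assert fams[0].members == {("g1", "A"), ("g2", "B"), ("g3", "C")}
    singles = build_families([], all_ids=["g1|A", "g2|B"])
    assert len(singles) == 2


def test_classification_recovers_simulator_truth(desk_sim):
    res = desk_sim
    cls, _ = classify_genomes(res.genomes, res.reference_db, res.plastid_panel)
    truth = res.truth.set_index(["genome_id", "feature_id"]).category
    mism = [k for k, cat in cls.categories.items() if truth.loc[k] != cat]
    assert mism == []


def test_category_totals_partition_the_cds_set(desk_sim):
    cls, _ = classify_genomes(desk_sim.genomes, desk_sim.reference_db,
                              desk_sim.plastid_panel)
    for gid, g in desk_sim.genomes.items():
        c = cls.counts(gid)
        assert sum(c.values()) == len(g.cds_features())


def test_norfan_count_rises_with_divergence():
    """As amino-acid divergence grows, homology detection fails and more
    hypothetical ORFs are classified as strain-specific nORFans."""
    levels = (0.2, 0.9, 1.6)
    means = []
    for d in levels:
        counts = []
        for seed in range(10):
            cfg = desk_config(seed=1000 + seed, aa_divergence=d,
                              n_genes_root=36, n_functional_root=14,
                              n_plastid_genes_root=8, n_rna_root=4,
                              mean_gene_len_aa=150)
            res = simulate(cfg)
            cls, _ = classify_genomes(res.genomes, res.reference_db,
                                      res.plastid_panel)
            counts.append(sum(1 for c in cls.categories.values()
                              if c == "nORFan"))
        means.append(np.mean(counts))
    assert means[0] < means[1] < means[2]


def test_classify_requires_nonempty_inputs():
    with pytest.raises(ValueError):
        classify_orfs({}, {"x": "MKV"})
    with pytest.raises(ValueError):
        classify_orfs({"g": {"f": "MKV"}}, {})


# ---------------------------------------------------------------------------
# synteny-guided label transfer

def _cls(categories, labels):
    r = ClassificationResult()
    r.categories.update(categories)
    r.labels.update(labels)
    return r


def test_label_transferred_to_syntenic_norf():
    fam = GeneFamily("f1", {("curv", "nuf2g"), ("para", "orfX")})
    res = _cls({("curv", "nuf2g"): "functional", ("para", "orfX"): "nORF"},
               {("curv", "nuf2g"): "nuf2"})
    out = synteny_transfer_labels(res, [fam])
    assert out.categories[("para", "orfX")] == "functional"
    assert out.labels[("para", "orfX")] == "nuf2"
    assert out.provenance[("para", "orfX")] == "synteny-transferred"


def test_family_without_functional_member_unchanged():
    fam = GeneFamily("f1", {("a", "x"), ("b", "y")})
    res = _cls({("a", "x"): "nORF", ("b", "y"): "nORF"}, {})
    out = synteny_transfer_labels(res, [fam])
    assert out.categories[("a", "x")] == "nORF"
    assert not out.conflicts


def test_conflicting_labels_flagged_not_resolved():
    fam = GeneFamily("f1", {("a", "x"), ("b", "y"), ("c", "z")})
    res = _cls({("a", "x"): "functional", ("b", "y"): "functional",
                ("c", "z"): "nORF"},
               {("a", "x"): "geneA", ("b", "y"): "geneB"})
    out = synteny_transfer_labels(res, [fam])
    assert out.categories[("c", "z")] == "nORF"  # untouched
    assert out.conflicts == [{"family_id": "f1", "labels": ["geneA", "geneB"]}]
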
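"""Simulator ground truth: determinism, conservation, planted mutations."""

import numpy as np
import pytest

from nmcomp.orfs import translate
from nmcomp.simulate import (ConfigError, SimulationConfig, apply_fragment_cuts,
                             desk_config, draw_cuts, events_on_path,
                             fragment_gene, replay, simulate)


def _seqs(genomes):
    return {n: [c.seq for c in g.chromosomes] for n, g in genomes.items()}


def test_all_rates_zero_gives_identical_genomes_and_empty_log():
    cfg = desk_config(seed=3, loss_rate=0.0, fragmentation_rate=0.0,
                      recombination_rate=0.0, duplication_rate=0.0,
                      aa_divergence=0.0, n_orfans_per_leaf=0,
                      telomere_motifs={l: "GA" * 4 + "GT" for l in
                                       ("para977", "paraKR", "ccac1634",
                                        "curvKR", "curv979")},
                      reduced_rdna_leaves=frozenset())
    res = simulate(cfg)
    assert res.events == []
    ref = _seqs(res.genomes)["curvKR"]
    assert all(s == ref for s in _seqs(res.genomes).values())


def test_determinism_byte_for_byte():
    a = simulate(desk_config(seed=9))
    b = simulate(desk_config(seed=9))
    assert _seqs(a.genomes) == _seqs(b.genomes)
    assert [e.to_json() for e in a.events] == [e.to_json() for e in b.events]


def test_event_log_replay_reproduces_leaves(desk_sim):
    replayed = replay(desk_sim)
    assert _seqs(replayed) == _seqs(desk_sim.genomes)
    for leaf, g in desk_sim.genomes.items():
        got = [(f.feature_id, f.start, f.end, f.strand) for f in
               replayed[leaf].iter_features()]
        want = [(f.feature_id, f.start, f.end, f.strand) for f in
                g.iter_features()]
        assert got == want


def test_gene_count_conservation_against_event_log(desk_sim):
    """leaf CDS count = root count - losses + fragment gains + duplication
    gains + ORFan gains along the root-to-leaf path."""
    res = desk_sim
    root_cds = sum(1 for ch in res.root_state.chroms for lo in ch.loci
                   if lo.kind == "CDS")
    paths = {"para977": ["anc_par", "para977"],
             "paraKR": ["anc_par", "paraKR"],
             "ccac1634": ["anc_cc", "ccac1634"],
             "curvKR": ["anc_cc", "anc_cur", "curvKR"],
             "curv979": ["anc_cc", "anc_cur", "curv979"]}
    for leaf, branches in paths.items():
        expected = root_cds
        for ev in res.events:
            if ev.branch not in branches:
                continue
            if ev.event_type == "loss":
                expected -= 1
            elif ev.event_type == "fragmentation":
                expected += ev.data["k"] - 1
            elif ev.event_type == "duplication":
                expected += ev.data["n"]
            elif ev.event_type == "gain":
                expected += 1
        assert len(desk_sim.genomes[leaf].cds_features()) == expected, leaf


def test_colorless_lineages_lose_more_plastid_genes():
    """With the loss multiplier active, colorless leaves retain fewer
    plastid-associated genes than photosynthetic leaves (20 seeds)."""
    colorless, colored = [], []
    for seed in range(20):
        res = simulate(desk_config(seed=seed))
        tr = res.truth
        pl = tr[tr.category == "plastid_associated"].groupby(
            "genome_id").family_id.nunique()
        colorless.append(pl.reindex(["para977", "paraKR", "ccac1634"]).mean())
        colored.append(pl.reindex(["curvKR", "curv979"]).mean())
    assert np.mean(colorless) < np.mean(colored)
    # photosynthetic leaves keep the full panel
    assert np.mean(colored) == pytest.approx(20.0)


def test_events_on_path_excludes_shared_history(desk_sim):
    evs = events_on_path(desk_sim, "curvKR", "curv979")
    assert {e.branch for e in evs} <= {"curvKR", "curv979"}
    evs2 = events_on_path(desk_sim, "para977", "ccac1634")
    assert {e.branch for e in evs2} <= {"anc_par", "para977", "anc_cc",
                                        "ccac1634"}


# ---------------------------------------------------------------------------
# fragment_gene

def _gene(n_codons, seed=0):
    rng = np.random.default_rng(seed)
    codons = ["".join(c) for c in zip(*[iter("ACGT" * 100)] * 3)]
    safe = [c for c in ("AAA", "AAT", "ATT", "TTA"[::-1], "GAA", "TTC", "AAC")
            if c not in ("TAA", "TAG", "TGA")]
    body = "".join(rng.choice(safe) for _ in range(n_codons - 1))
    return "ATG" + body + "TAA"


def test_premature_stop_split_in_half():
    dna = _gene(300)
    rng = np.random.default_rng(1)
    mutated, bounds, cuts = fragment_gene(dna, 2, "premature_stop", rng)
    assert len(bounds) == 2
    assert len(mutated) == len(dna)  # no length change
    for s, e in bounds:
        frag = mutated[s:e]
        aa = translate(frag)
        assert aa.startswith("M") and aa.endswith("*") and "*" not in aa[:-1]
        assert len(aa) - 1 >= 52


def test_frameshift_deletion_shifts_downstream_frame_by_one():
    dna = _gene(300, seed=2)
    protein = translate(dna)[:-1]
    rng = np.random.default_rng(3)
    mutated, bounds, cuts = fragment_gene(dna, 2, "frameshift_deletion", rng)
    assert len(mutated) == len(dna) - 1  # one base deleted
    (s1, e1), (s2, e2) = bounds
    assert (s2 - s1) % 3 == 2  # downstream frame differs by -1 nt
    aa2 = translate(mutated[s2:e2])
    # downstream fragment re-encodes the C-terminus of the original protein
    assert aa2[1:-1] == protein[cuts[0] + 2:]
    aa1 = translate(mutated[s1:e1])
    assert aa1[:-1] == protein[:cuts[0]]


def test_six_way_fragmentation_of_long_gene():
    dna = _gene(900, seed=4)
    rng = np.random.default_rng(5)
    mutated, bounds, cuts = fragment_gene(dna, 6, "premature_stop", rng)
    assert len(bounds) == 6
    total_aa = sum((e - s) // 3 - 1 for s, e in bounds)
    assert total_aa == pytest.approx(899, abs=6)  # lengths add up
    for s, e in bounds:
        aa = translate(mutated[s:e])
        assert aa.startswith("M") and aa.endswith("*")


def test_fragment_gene_rejects_too_short_genes():
    with pytest.raises(ValueError):
        fragment_gene(_gene(80), 2, "premature_stop", np.random.default_rng(0))
    with pytest.raises(ValueError):
        fragment_gene(_gene(300), 1, "premature_stop", np.random.default_rng(0))


def test_apply_fragment_cuts_is_deterministic():
    dna = _gene(400, seed=6)
    cuts = draw_cuts(np.random.default_rng(7), 399, 3)
    assert apply_fragment_cuts(dna, cuts, "premature_stop") == \
        apply_fragment_cuts(dna, cuts, "premature_stop")


# ---------------------------------------------------------------------------
# configuration validation

def test_negative_rates_rejected():
    with pytest.raises(ConfigError):
        SimulationConfig(loss_rate=-0.1)


def test_rates_implying_certain_loss_rejected():
    cfg = desk_config(seed=0, loss_rate=4.0)  # p = 1.2 on a 0.3 branch
    with pytest.raises(ConfigError):
        simulate(cfg)
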
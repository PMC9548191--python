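"""Forward simulator of nucleomorph genome evolution on a fixed 5-leaf tree.

The simulator emulates the processes that shape reduced nucleomorph genomes
within a single genus: a gene-dense 3-chromosome ancestor with sub-telomeric
rDNA operons and short tandem telomere repeats evolves along a species tree
whose colorless (non-photosynthetic) lineages experience strongly elevated
loss of photosynthesis-related plastid-associated genes, while all lineages
accumulate amino-acid divergence, occasional gene loss, ORF fragmentation by
single-base deletions or premature stop codons, sub-telomeric
inter-chromosomal recombination, and small segmental duplications.

Every stochastic decision is recorded in an event log whose replay on the
root genome reproduces each leaf genome byte-for-byte, and every gene
carries its true family id, so downstream detection stages can be scored
against exact ground truth.

Gene sequences are random codon strings with a configurable GC bias; no
attempt is made to model real protein families.  rDNA operons are opaque
RNA features at chromosome ends.  Recombination breakpoints fall only in
intergenic gaps, so translocation never splits genes - fragmentation is its
own process.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .census import load_panel
from .genome import Chromosome, GeneFeature, Genome, revcomp
from .homology import GeneFamily
from .orfs import translate

LEAVES = ("para977", "paraKR", "ccac1634", "curvKR", "curv979")
COLORLESS = frozenset({"para977", "paraKR", "ccac1634"})

#: telomere repeat literals observed in the five strains
DEFAULT_TELOMERES = {
    "para977": "GA" * 9,
    "paraKR": "GA" * 16,
    "ccac1634": "T" + "GTA" * 3 + "A" + "G" * 6 + "AGA" + "AG" * 6 + "G" * 3 + "A" + "G" * 5,
    "curvKR": "GA" * 4 + "GT",
    "curv979": "GA" * 3 + "GT",
}

MIN_FRAG_AA = 52  # each fragment must clear the 50-aa ORF-calling floor

_NAMED_FUNCTIONAL = (
    "nuf2", "sf3b3-like", "sf3b1-like", "rarA", "cdc5-like",
    "BRSK", "nol10", "pab2", "trf", "rfc2", "rps9", "rps17",
)


@dataclass
class TreeNode:
    name: str
    length: float                     # branch length to parent, divergence units
    colorless: bool                   # lineage is colorless along this branch
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self):
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def default_tree() -> TreeNode:
    """((para977, paraKR), (ccac1634, (curvKR, curv979))); photosynthesis was
    lost independently on the paramecium stem and the ccac1634 branch."""
    return TreeNode("root", 0.0, False, [
        TreeNode("anc_par", 0.30, True, [
            TreeNode("para977", 0.10, True),
            TreeNode("paraKR", 0.10, True),
        ]),
        TreeNode("anc_cc", 0.30, False, [
            TreeNode("ccac1634", 0.30, True),
            TreeNode("anc_cur", 0.15, False, [
                TreeNode("curvKR", 0.10, False),
                TreeNode("curv979", 0.10, False),
            ]),
        ]),
    ])


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of one simulation run; the seed fixes the output exactly.

    Rates are per gene (or per genome for recombination/duplication) per
    unit branch length.  Defaults are calibrated so that leaf genomes land
    in the empirically observed ranges for Cryptomonas nucleomorphs:
    ~0.49-0.66 Mb over 3 chromosomes, ~410-570 genes, 84-87 % coding, GC
    ~24-28 %, colorless leaves retaining ~17-19 of 31 plastid-associated
    genes while photosynthetic leaves keep all 31.
    """

    seed: int = 0
    n_genes_root: int = 570
    n_functional_root: int = 330          # includes the plastid panel
    n_plastid_genes_root: int = 31
    n_rna_root: int = 45
    chromosome_count: int = 3
    mean_gene_len_aa: int = 300
    min_gene_len_aa: int = 60
    mean_intergenic_bp: int = 150
    min_intergenic_bp: int = 30
    gc_target: float = 0.26
    loss_rate: float = 0.2
    photosynthesis_loss_multiplier: float = 15.0
    fragmentation_rate: float = 0.1
    fragments_k_range: tuple = (2, 6)
    recombination_rate: float = 0.5       # events per genome per unit length
    duplication_rate: float = 0.2
    dup_run_genes: int = 5
    aa_divergence: float = 0.2            # substitutions per site per unit length
    n_orfans_per_leaf: int = 10
    recomb_segment_genes: tuple = (2, 6)
    rdna_operon_bp: int = 4500
    rdna_5s_bp: int = 120
    trna_bp: int = 72
    telomere_copies: int = 5
    telomere_motifs: dict = field(default_factory=lambda: dict(DEFAULT_TELOMERES))
    reduced_rdna_leaves: frozenset = frozenset({"para977", "paraKR"})

    def __post_init__(self):
        rates = (self.loss_rate, self.fragmentation_rate, self.recombination_rate,
                 self.duplication_rate, self.aa_divergence,
                 self.photosynthesis_loss_multiplier)
        if any(r < 0 for r in rates):
            raise ConfigError("all rates must be >= 0")
        if self.n_functional_root + self.n_rna_root > self.n_genes_root:
            raise ConfigError("functional + RNA genes exceed n_genes_root")
        if self.n_plastid_genes_root > self.n_functional_root:
            raise ConfigError("plastid genes exceed functional genes")

    @property
    def n_hypothetical_root(self) -> int:
        return self.n_genes_root - self.n_functional_root - self.n_rna_root


def desk_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A scaled-down configuration for fast desk-scale experiments/tests.

    Same processes and rate defaults as the full configuration, ~10x fewer
    and shorter genes."""
    base = dict(
        seed=seed, n_genes_root=64, n_functional_root=30,
        n_plastid_genes_root=20, n_rna_root=6, mean_gene_len_aa=200,
        min_gene_len_aa=60, mean_intergenic_bp=100, dup_run_genes=3,
        n_orfans_per_leaf=3, rdna_operon_bp=600, rdna_5s_bp=120,
    )
    base.update(overrides)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# symbolic genome state

@dataclass
class SubFeature:
    feature_id: str
    offset: int            # bp within the locus, strand-local
    end: int
    family_id: str
    label: str | None = None


@dataclass
class Locus:
    locus_id: str
    dna: str               # strand-local sequence (CDS: ATG..stop)
    strand: str
    kind: str              # CDS | tRNA
    features: list[SubFeature]
    fragmented: bool = False


@dataclass
class ChromState:
    chrom_id: str
    spacers: list[str]     # len(loci) + 1, spacer i precedes locus i
    loci: list[Locus]


@dataclass
class GenomeState:
    chroms: list[ChromState]

    def locus_index(self):
        return {lo.locus_id: (ci, li)
                for ci, ch in enumerate(self.chroms)
                for li, lo in enumerate(ch.loci)}

    def cds_loci(self):
        return [lo for ch in self.chroms for lo in ch.loci if lo.kind == "CDS"]


@dataclass
class Event:
    branch: str
    event_type: str        # divergence|loss|fragmentation|recombination|duplication|gain
    data: dict

    def to_json(self) -> str:
        return json.dumps({"branch": self.branch, "event_type": self.event_type,
                           "data": self.data}, default=list)


@dataclass
class SimulationResult:
    config: SimulationConfig
    tree: TreeNode
    root_state: GenomeState
    leaf_states: dict[str, GenomeState]
    genomes: dict[str, Genome]
    events: list[Event]
    truth: pd.DataFrame
    families: list[GeneFamily]
    reference_db: dict[str, str]
    plastid_panel: set[str]


# ---------------------------------------------------------------------------
# sequence generation helpers

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")


def _codon_sampler(gc: float):
    codons = ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    base_p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    probs = np.array([base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in codons])
    keep = np.array([c not in _STOPS for c in codons])
    probs = np.where(keep, probs, 0.0)
    probs /= probs.sum()
    codons = np.array(codons)
    return codons, probs


def _random_dna(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _random_gene(rng, n_aa: int, codons, probs) -> str:
    body = "".join(rng.choice(codons, size=n_aa - 1, p=probs))
    return "ATG" + body + "TAA"


def _mark_spacer(sp: str) -> str:
    """Plant strand-appropriate in-frame stops at both spacer boundaries so
    that every intact gene is exactly recoverable by the ORF caller."""
    if len(sp) < 7:
        sp = sp + "T" * (7 - len(sp))
    return "TTA" + sp[3:-3] + "TAA"


# ---------------------------------------------------------------------------
# gene fragmentation

def apply_fragment_cuts(dna: str, cuts: list[int], disruption: str):
    """Deterministically fragment a CDS at the given cut codons.

    Returns (mutated_dna, fragment_bounds) where bounds are strand-local
    half-open bp intervals, each an exact ATG..stop ORF.  premature_stop
    keeps all fragments in frame; frameshift_deletion removes one base per
    junction so each downstream fragment's frame differs by -1 nt.
    """
    if len(dna) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    codons = [dna[i:i + 3] for i in range(0, len(dna), 3)]
    n = len(codons) - 1  # coding codons, codons[n] is the stop
    if any(not 0 < j < n - 1 for j in cuts) or sorted(cuts) != list(cuts):
        raise ValueError("invalid cut positions")
    k = len(cuts) + 1
    if disruption == "premature_stop":
        for j in cuts:
            codons[j] = "TAA"
            codons[j + 1] = "ATG"
        starts = [0] + [j + 1 for j in cuts]
        ends = [j + 1 for j in cuts] + [n + 1]
        bounds = [(3 * s, 3 * e) for s, e in zip(starts, ends)]
        return "".join(codons), bounds
    if disruption == "frameshift_deletion":
        cutset = set(cuts)
        for j in cuts:
            codons[j + 1] = "ATG"
        pieces = ["TA" if i in cutset else c for i, c in enumerate(codons)]
        mutated = "".join(pieces)
        bounds = []
        for i in range(k):
            s_codon = 0 if i == 0 else cuts[i - 1] + 1
            start = 3 * s_codon - i
            end = (3 * cuts[i] + 3 - i) if i < k - 1 else len(mutated)
            bounds.append((start, end))
        return mutated, bounds
    raise ValueError(f"unknown disruption type {disruption!r}")


def draw_cuts(rng, n_codons: int, k: int, min_frag_aa: int = MIN_FRAG_AA) -> list[int]:
    slack = n_codons - 1 - k * min_frag_aa - 2 * (k - 1)
    if slack < 0:
        raise ValueError(f"gene of {n_codons} codons too short for k={k} fragments")
    extras = np.sort(rng.integers(0, slack + 1, size=k - 1))
    return [min_frag_aa + i * (min_frag_aa + 2) + int(extras[i]) for i in range(k - 1)]


def fragment_gene(dna: str, k: int, disruption: str, rng,
                  min_frag_aa: int = MIN_FRAG_AA):
    """Fragment one CDS into k consecutive ORFs (public sampling wrapper)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(dna) // 3 - 1
    cuts = draw_cuts(rng, n, k, min_frag_aa)
    mutated, bounds = apply_fragment_cuts(dna, cuts, disruption)
    return mutated, bounds, cuts


def max_fragments(n_codons: int, min_frag_aa: int = MIN_FRAG_AA) -> int:
    return (n_codons + 1) // (min_frag_aa + 2)


# ---------------------------------------------------------------------------
# root genome

def build_root(cfg: SimulationConfig, rng) -> tuple[GenomeState, dict[str, str]]:
    codons, probs = _codon_sampler(cfg.gc_target)
    panel = load_panel("plastid_all")
    if cfg.n_plastid_genes_root > len(panel):
        raise ConfigError(f"at most {len(panel)} plastid labels available")
    labels = list(panel[:cfg.n_plastid_genes_root])
    n_other = cfg.n_functional_root - cfg.n_plastid_genes_root
    named = [n for n in _NAMED_FUNCTIONAL][:n_other]
    labels += named + [f"fun{i:03d}" for i in range(n_other - len(named))]
    specs = [("CDS", lab, lab) for lab in labels]
    specs += [("CDS", None, f"hyp{i:03d}") for i in range(cfg.n_hypothetical_root)]
    specs += [("tRNA", f"trn{i:02d}", f"trn{i:02d}") for i in range(cfg.n_rna_root)]
    order = rng.permutation(len(specs))
    shape = 3.0
    chroms = []
    per = int(np.ceil(len(specs) / cfg.chromosome_count))
    reference: dict[str, str] = {}
    for ci in range(cfg.chromosome_count):
        idxs = order[ci * per:(ci + 1) * per]
        loci = []
        spacers = []
        for li, si in enumerate(idxs):
            kind, label, family = specs[si]
            spacers.append(_mark_spacer(_random_dna(
                rng, cfg.min_intergenic_bp + int(rng.gamma(
                    2.0, max(1.0, (cfg.mean_intergenic_bp - cfg.min_intergenic_bp) / 2.0))),
                cfg.gc_target)))
            lid = f"g{si:04d}"
            if kind == "CDS":
                n_aa = max(cfg.min_gene_len_aa,
                           int(rng.gamma(shape, cfg.mean_gene_len_aa / shape)))
                dna = _random_gene(rng, n_aa, codons, probs)
                if label is not None:
                    reference[label] = translate(dna)[:-1]
            else:
                dna = _random_dna(rng, cfg.trna_bp, cfg.gc_target)
            strand = "+" if rng.random() < 0.5 else "-"
            loci.append(Locus(lid, dna, strand, kind,
                              [SubFeature(lid, 0, len(dna), family, label)]))
        spacers.append(_mark_spacer(_random_dna(rng, cfg.min_intergenic_bp + 20,
                                                cfg.gc_target)))
        chroms.append(ChromState(f"chr{ci + 1}", spacers, loci))
    return GenomeState(chroms), reference


# ---------------------------------------------------------------------------
# event application (shared by simulation and replay)

def apply_event(state: GenomeState, ev: Event, cfg: SimulationConfig) -> None:
    d = ev.data
    if ev.event_type == "divergence":
        idx = state.locus_index()
        for locus_id, codon_i, new_codon in d["subs"]:
            ci, li = idx[locus_id]
            lo = state.chroms[ci].loci[li]
            p = 3 * int(codon_i)
            lo.dna = lo.dna[:p] + new_codon + lo.dna[p + 3:]
    elif ev.event_type == "loss":
        ci, li = state.locus_index()[d["locus_id"]]
        ch = state.chroms[ci]
        ch.loci.pop(li)
        ch.spacers.pop(li)
    elif ev.event_type == "fragmentation":
        ci, li = state.locus_index()[d["locus_id"]]
        lo = state.chroms[ci].loci[li]
        mutated, bounds = apply_fragment_cuts(lo.dna, list(d["cuts"]), d["disruption"])
        fam = lo.features[0].family_id
        lo.dna = mutated
        lo.features = [
            SubFeature(f"{lo.locus_id}_f{i + 1}", s, e, fam, lo.features[0].label)
            for i, (s, e) in enumerate(bounds)
        ]
        lo.fragmented = True
    elif ev.event_type == "recombination":
        _apply_recombination(state, d)
    elif ev.event_type == "duplication":
        _apply_duplication(state, d)
    elif ev.event_type == "gain":
        ch = state.chroms[d["chrom_index"]]
        ii = d["insert_idx"]
        lo = Locus(d["locus_id"], d["dna"], d["strand"], "CDS",
                   [SubFeature(d["locus_id"], 0, len(d["dna"]), d["family_id"])])
        ch.loci.insert(ii, lo)
        ch.spacers.insert(ii, _mark_spacer(d["spacer"]))
    else:
        raise ValueError(f"unknown event type {ev.event_type}")


def _flip_locus(lo: Locus) -> Locus:
    out = copy.deepcopy(lo)
    out.strand = "+" if lo.strand == "-" else "-"
    return out


def _take_segment(ch: ChromState, side: str, m: int):
    """Remove m terminal loci; return the segment in terminus-first form
    (list of (spacer, locus) pairs reading from the chromosome end inward)."""
    n = len(ch.loci)
    if side == "left":
        seg = list(zip(ch.spacers[:m], ch.loci[:m]))
        ch.spacers = ch.spacers[m:]
        ch.loci = ch.loci[m:]
        return seg
    seg = [(revcomp(ch.spacers[n - j]), _flip_locus(ch.loci[n - 1 - j]))
           for j in range(m)]
    ch.loci = ch.loci[:n - m]
    ch.spacers = ch.spacers[:n - m + 1]
    return seg


def _put_segment(ch: ChromState, side: str, seg) -> None:
    if side == "left":
        ch.spacers = [sp for sp, _ in seg] + ch.spacers
        ch.loci = [lo for _, lo in seg] + ch.loci
    else:
        ch.loci = ch.loci + [_flip_locus(lo) for _, lo in reversed(seg)]
        ch.spacers = ch.spacers + [revcomp(sp) for sp, _ in reversed(seg)]


def _apply_recombination(state: GenomeState, d: dict) -> None:
    (ca, sa), (cb, sb) = tuple(d["end_a"]), tuple(d["end_b"])
    cha = next(c for c in state.chroms if c.chrom_id == ca)
    chb = next(c for c in state.chroms if c.chrom_id == cb)
    seg_a = _take_segment(cha, sa, d["n_a"])
    seg_b = _take_segment(chb, sb, d["n_b"])
    _put_segment(cha, sa, seg_b)
    _put_segment(chb, sb, seg_a)


def _apply_duplication(state: GenomeState, d: dict) -> None:
    src = next(c for c in state.chroms if c.chrom_id == d["src_chrom"])
    dst = next(c for c in state.chroms if c.chrom_id == d["dst_chrom"])
    s, n = d["start_idx"], d["n"]
    tag = d["tag"]
    copies = []
    spacers = []
    for lo, sp in zip(src.loci[s:s + n], src.spacers[s:s + n]):
        cp = copy.deepcopy(lo)
        cp.locus_id = f"{lo.locus_id}.{tag}"
        for f in cp.features:
            f.feature_id = f"{f.feature_id}.{tag}"
        copies.append(cp)
        spacers.append(sp)
    ii = d["insert_idx"]
    dst.loci = dst.loci[:ii] + copies + dst.loci[ii:]
    dst.spacers = dst.spacers[:ii] + spacers + dst.spacers[ii:]


# ---------------------------------------------------------------------------
# branch evolution

def _loss_probability(cfg, lo: Locus, length: float, colorless: bool,
                      plastid_panel: set[str], core_panel: set[str]) -> float:
    label = lo.features[0].label
    if label in plastid_panel:
        if label in core_panel:
            return 0.0  # core plastid genes are retained in every lineage
        if colorless:
            p = cfg.loss_rate * cfg.photosynthesis_loss_multiplier * length
        else:
            return 0.0  # photosynthesis genes are under selection while colored
    else:
        p = cfg.loss_rate * length
    if p >= 1.0:
        raise ConfigError(
            f"loss probability {p:.2f} >= 1 on branch of length {length}; "
            "rates imply >100% expected loss")
    return p


def evolve_branch(state: GenomeState, node: TreeNode, cfg: SimulationConfig,
                  rng, panels) -> list[Event]:
    plastid_panel, core_panel = panels
    events: list[Event] = []
    length = node.length
    codons, probs = _codon_sampler(cfg.gc_target)
    # amino-acid divergence (i.i.d. per codon, flat kernel)
    p_sub = min(0.95, cfg.aa_divergence * length)
    subs = []
    if p_sub > 0:
        for ch in state.chroms:
            for lo in ch.loci:
                if lo.kind != "CDS" or lo.fragmented:
                    continue
                n = len(lo.dna) // 3 - 2
                if n <= 0:
                    continue
                mask = np.nonzero(rng.random(n) < p_sub)[0]
                if mask.size:
                    newc = rng.choice(codons, size=mask.size, p=probs)
                    subs.extend((lo.locus_id, int(i) + 1, str(c))
                                for i, c in zip(mask, newc))
    if subs:
        ev = Event(node.name, "divergence", {"subs": subs})
        apply_event(state, ev, cfg)
        events.append(ev)
    # gene loss
    for lo in list(state.cds_loci()):
        p = _loss_probability(cfg, lo, length, node.colorless,
                              plastid_panel, core_panel)
        if p > 0 and rng.random() < p:
            ev = Event(node.name, "loss", {"locus_id": lo.locus_id,
                                           "label": lo.features[0].label,
                                           "family_id": lo.features[0].family_id})
            apply_event(state, ev, cfg)
            events.append(ev)
    # ORF fragmentation
    p_frag = min(0.95, cfg.fragmentation_rate * length)
    k_lo, k_hi = cfg.fragments_k_range
    if p_frag > 0:
        for lo in list(state.cds_loci()):
            if lo.fragmented:
                continue
            n = len(lo.dna) // 3 - 1
            kmax = min(k_hi, max_fragments(n))
            if kmax < max(2, k_lo) or rng.random() >= p_frag:
                continue
            k = int(rng.integers(max(2, k_lo), kmax + 1))
            disruption = ("premature_stop" if rng.random() < 0.5
                          else "frameshift_deletion")
            cuts = draw_cuts(rng, n, k)
            ev = Event(node.name, "fragmentation",
                       {"locus_id": lo.locus_id, "k": k, "cuts": cuts,
                        "disruption": disruption,
                        "family_id": lo.features[0].family_id})
            apply_event(state, ev, cfg)
            events.append(ev)
    # sub-telomeric inter-chromosomal recombination
    m_lo, m_hi = cfg.recomb_segment_genes
    for _ in range(rng.poisson(cfg.recombination_rate * length)):
        ends = [(c.chrom_id, side) for c in state.chroms for side in ("left", "right")]
        ia, ib = rng.choice(len(ends), size=2, replace=False)
        (ca, sa), (cb, sb) = ends[ia], ends[ib]
        if ca == cb:
            continue
        avail_a = len(next(c for c in state.chroms if c.chrom_id == ca).loci)
        avail_b = len(next(c for c in state.chroms if c.chrom_id == cb).loci)
        n_a = int(min(rng.integers(m_lo, m_hi + 1), avail_a // 3))
        n_b = int(min(rng.integers(m_lo, m_hi + 1), avail_b // 3))
        if n_a < 1 or n_b < 1:
            continue
        ev = Event(node.name, "recombination",
                   {"end_a": (ca, sa), "end_b": (cb, sb), "n_a": n_a, "n_b": n_b})
        apply_event(state, ev, cfg)
        events.append(ev)
    # segmental duplication
    for di in range(rng.poisson(cfg.duplication_rate * length)):
        src = state.chroms[rng.integers(len(state.chroms))]
        n = min(cfg.dup_run_genes, max(1, len(src.loci) // 4))
        if len(src.loci) < n + 2:
            continue
        start = int(rng.integers(0, len(src.loci) - n + 1))
        dst = state.chroms[rng.integers(len(state.chroms))]
        for _attempt in range(10):
            ii = int(rng.integers(0, len(dst.loci) + 1))
            if dst.chrom_id != src.chrom_id or not (start - 1 <= ii <= start + n + 1):
                break
        else:
            continue
        fams = [lo.features[0].family_id for lo in src.loci[start:start + n]]
        ev = Event(node.name, "duplication",
                   {"src_chrom": src.chrom_id, "start_idx": start, "n": n,
                    "dst_chrom": dst.chrom_id, "insert_idx": ii,
                    "tag": f"{node.name}d{di}", "families": fams})
        apply_event(state, ev, cfg)
        events.append(ev)
    # strain-specific ORFan gains on terminal branches
    if not node.children and cfg.n_orfans_per_leaf > 0:
        codons2, probs2 = codons, probs
        for oi in range(cfg.n_orfans_per_leaf):
            n_aa = max(cfg.min_gene_len_aa,
                       int(rng.gamma(2.0, cfg.mean_gene_len_aa / 3.0)))
            dna = _random_gene(rng, n_aa, codons2, probs2)
            ci = int(rng.integers(len(state.chroms)))
            ii = int(rng.integers(0, len(state.chroms[ci].loci) + 1))
            lid = f"orfan_{node.name}_{oi}"
            ev = Event(node.name, "gain",
                       {"chrom_index": ci, "insert_idx": ii, "locus_id": lid,
                        "dna": dna, "strand": "+" if rng.random() < 0.5 else "-",
                        "family_id": f"fam_{lid}",
                        "spacer": _random_dna(rng, cfg.mean_intergenic_bp,
                                              cfg.gc_target)})
            apply_event(state, ev, cfg)
            events.append(ev)
    return events


# ---------------------------------------------------------------------------
# realization of an annotated Genome from symbolic state

def _rdna_pattern(cfg: SimulationConfig, leaf: str, chrom_id: str):
    if leaf in cfg.reduced_rdna_leaves and chrom_id in ("chr1", "chr2"):
        return ("5S", None)
    return ("operon", "operon")


def _rdna_seqs(cfg: SimulationConfig):
    # fixed derivation from the config seed (stable across processes)
    rng = np.random.default_rng((cfg.seed * 2654435761 + 97) % 2**31)
    return {"operon": _random_dna(rng, cfg.rdna_operon_bp, cfg.gc_target),
            "5S": _random_dna(rng, cfg.rdna_5s_bp, cfg.gc_target)}


def realize(state: GenomeState, leaf: str, cfg: SimulationConfig,
            categories: dict[str, str], plastid_panel: set[str]) -> Genome:
    """Assemble chromosome sequences and annotated features for one leaf."""
    rdna = _rdna_seqs(cfg)
    tel = cfg.telomere_motifs[leaf] * cfg.telomere_copies
    chroms = []
    for ch in state.chroms:
        parts: list[str] = [tel]
        pos = len(tel)
        feats: list[GeneFeature] = []
        left, right = _rdna_pattern(cfg, leaf, ch.chrom_id)
        if left:
            seq = rdna[left]
            feats.append(GeneFeature(f"rdna_{ch.chrom_id}_L", ch.chrom_id, pos,
                                     pos + len(seq), "+", "rRNA",
                                     product="rDNA operon" if left == "operon"
                                     else "5S rRNA"))
            parts.append(seq)
            pos += len(seq)
        for sp, lo in zip(ch.spacers, ch.loci):
            parts.append(sp)
            pos += len(sp)
            L = len(lo.dna)
            realized = lo.dna if lo.strand == "+" else revcomp(lo.dna)
            for f in lo.features:
                if lo.strand == "+":
                    gs, ge = pos + f.offset, pos + f.end
                else:
                    gs, ge = pos + L - f.end, pos + L - f.offset
                if lo.kind == "CDS":
                    cds = lo.dna[f.offset:f.end]
                    protein = translate(cds[:len(cds) // 3 * 3])[:-1]
                    cat = _category(f, categories, plastid_panel)
                else:
                    protein, cat = None, "unclassified"
                feats.append(GeneFeature(f.feature_id, ch.chrom_id, gs, ge,
                                         lo.strand, "CDS" if lo.kind == "CDS"
                                         else lo.kind, category=cat,
                                         product=f.label, protein=protein,
                                         family_id=f.family_id))
            parts.append(realized)
            pos += L
        parts.append(ch.spacers[-1])
        pos += len(ch.spacers[-1])
        if right:
            seq = rdna[right]
            feats.append(GeneFeature(f"rdna_{ch.chrom_id}_R", ch.chrom_id, pos,
                                     pos + len(seq), "-", "rRNA",
                                     product="rDNA operon" if right == "operon"
                                     else "5S rRNA"))
            parts.append(seq)
            pos += len(seq)
        parts.append(revcomp(tel))
        chroms.append(Chromosome(ch.chrom_id, "".join(parts), feats))
    return Genome(leaf, chroms, photosynthetic=leaf not in COLORLESS)


def _category(f: SubFeature, categories: dict[str, str], plastid_panel) -> str:
    if f.label is not None:
        return "plastid_associated" if f.label in plastid_panel else "functional"
    return categories.get(f.family_id, "nORFan")


def _finalize(leaf_states: dict[str, GenomeState], cfg: SimulationConfig,
              plastid_panel: set[str]):
    presence: dict[str, set[str]] = {}
    for leaf, st in leaf_states.items():
        for lo in st.cds_loci():
            for f in lo.features:
                presence.setdefault(f.family_id, set()).add(leaf)
    categories = {fam: ("nORF" if len(ls) >= 2 else "nORFan")
                  for fam, ls in presence.items()}
    genomes = {leaf: realize(st, leaf, cfg, categories, plastid_panel)
               for leaf, st in leaf_states.items()}
    rows = []
    members: dict[str, set] = {}
    labels: dict[str, str] = {}
    for leaf, g in genomes.items():
        for f in g.cds_features():
            rows.append({"genome_id": leaf, "feature_id": f.feature_id,
                         "chromosome_id": f.chromosome_id,
                         "family_id": f.family_id, "category": f.category,
                         "label": f.product})
            members.setdefault(f.family_id, set()).add((leaf, f.feature_id))
            if f.product:
                labels[f.family_id] = f.product
    truth = pd.DataFrame(rows).sort_values(
        ["genome_id", "chromosome_id", "feature_id"]).reset_index(drop=True)
    families = [GeneFamily(fam, mem, labels.get(fam))
                for fam, mem in sorted(members.items())]
    return genomes, truth, families


# ---------------------------------------------------------------------------
# top level

def simulate(config: SimulationConfig, tree: TreeNode | None = None) -> SimulationResult:
    """Run the forward simulation; deterministic under config.seed."""
    tree = tree or default_tree()
    rng = np.random.default_rng(config.seed)
    plastid_panel = set(load_panel("plastid_all")[:config.n_plastid_genes_root])
    core_panel = set(load_panel("plastid_core")) & plastid_panel
    root, reference = build_root(config, rng)
    events: list[Event] = []
    leaf_states: dict[str, GenomeState] = {}

    def rec(node: TreeNode, state: GenomeState) -> None:
        for child in node.children:
            st = copy.deepcopy(state)
            events.extend(evolve_branch(st, child, config, rng,
                                        (plastid_panel, core_panel)))
            if child.children:
                rec(child, st)
            else:
                leaf_states[child.name] = st

    rec(tree, root)
    genomes, truth, families = _finalize(leaf_states, config, plastid_panel)
    return SimulationResult(config, tree, root, leaf_states, genomes, events,
                            truth, families, reference, plastid_panel)


def replay(result: SimulationResult) -> dict[str, Genome]:
    """Re-apply the event log to the root genome and re-realize every leaf."""
    cfg = result.config
    by_branch: dict[str, list[Event]] = {}
    for ev in result.events:
        by_branch.setdefault(ev.branch, []).append(ev)
    leaf_states: dict[str, GenomeState] = {}

    def rec(node: TreeNode, state: GenomeState) -> None:
        for child in node.children:
            st = copy.deepcopy(state)
            for ev in by_branch.get(child.name, []):
                apply_event(st, ev, cfg)
            if child.children:
                rec(child, st)
            else:
                leaf_states[child.name] = st

    rec(result.tree, copy.deepcopy(result.root_state))
    genomes, _, _ = _finalize(leaf_states, cfg, result.plastid_panel)
    return genomes


def apply_extra_events(result: SimulationResult, leaf: str,
                       events: list[Event]):
    """Apply additional (planted) events to one leaf and re-realize all leaves.

    Returns (genomes, truth, families) reflecting the extra events; the
    input result is not modified.  Useful for constructing controlled
    rearrangement scenarios on top of a simulated background.
    """
    states = {k: copy.deepcopy(v) for k, v in result.leaf_states.items()}
    for ev in events:
        apply_event(states[leaf], ev, result.config)
    return _finalize(states, result.config, result.plastid_panel)


def write_events_jsonl(events: list[Event], path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(ev.to_json() + "\n")


def events_on_path(result: SimulationResult, leaf_a: str, leaf_b: str) -> list[Event]:
    """Events on the tree path between two leaves (exclusive of shared history)."""
    def path_to(leaf):
        out = []

        def walk(node, acc):
            if node.name == leaf:
                out.extend(acc)
                return True
            return any(walk(c, acc + [c.name]) for c in node.children)

        walk(result.tree, [])
        return out

    pa, pb = set(path_to(leaf_a)), set(path_to(leaf_b))
    branches = pa ^ pb
    return [ev for ev in result.events if ev.branch in branches]
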
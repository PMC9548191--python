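"""All-vs-all protein similarity, family clustering, and ORF classification.

Rather than a heuristic database search, pairwise similarity is computed by
exact Smith-Waterman local alignment (BLOSUM62, affine gaps 11/1) on every
candidate pair; nucleomorph proteomes are small enough that this is cheap.
Candidate pairs are pre-screened by shared 5-mer count, which plays the
role of a seeding stage: even under the strongly AT-biased amino-acid
composition of nucleomorph proteomes, unrelated proteins essentially never
share eight exact 5-mers, so the permissive e-value threshold of 0.05 is
only ever applied to pairs with genuine word-level similarity, while
homologs at the divergences of interest share tens of identical words.

E-values use fixed gapped Karlin-Altschul constants for BLOSUM62/11/1
(lambda = 0.267, K = 0.041) with search space m*n on raw lengths:
bitscore = (lambda*raw - ln K)/ln 2 and evalue = m*n*2**(-bitscore).

Classification follows the three-way scheme used for nucleomorph genomes:
an ORF whose best significant hit is a labeled functional reference protein
is *functional* (and *plastid_associated* when the label is on the plastid
panel); otherwise an ORF with a significant hit in another nucleomorph
genome is a conserved nucleomorph ORF (*nORF*); otherwise it is a
strain-specific *nORFan*.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import biotite.sequence as bseq
import biotite.sequence.align as balign

LAMBDA = 0.267
KA_K = 0.041
_MATRIX = balign.SubstitutionMatrix.std_protein_matrix()  # BLOSUM62

#: biotite charges open for the first gap position and extend for each further
#: one, so (-12, -1) reproduces the BLAST 11/1 convention (gap of length l
#: costs 11 + l).
_GAP_PENALTY = (-12, -1)


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    raw_score: int
    bitscore: float
    evalue: float
    q_interval: tuple[int, int]  # aligned span on query, aa, half-open
    s_interval: tuple[int, int]
    pct_identity: float


def bitscore(raw: float) -> float:
    return (LAMBDA * raw - math.log(KA_K)) / math.log(2)


def evalue(raw: float, m: int, n: int) -> float:
    return m * n * 2.0 ** (-bitscore(raw))


def align_proteins(q: str, s: str, query_id: str = "q", subject_id: str = "s",
                   evalue_max: float = 0.05) -> HomologyHit | None:
    """Optimal local alignment of two proteins; None if not significant."""
    if not q or not s:
        raise ValueError("empty protein sequence")
    qs = bseq.ProteinSequence(q.replace("*", "X"))
    ss = bseq.ProteinSequence(s.replace("*", "X"))
    alns = balign.align_optimal(qs, ss, _MATRIX, gap_penalty=_GAP_PENALTY,
                                local=True, max_number=1)
    aln = alns[0]
    raw = int(aln.score)
    ev = evalue(raw, len(q), len(s))
    if ev > evalue_max:
        return None
    trace = aln.trace
    qcols = trace[:, 0][trace[:, 0] >= 0]
    scols = trace[:, 1][trace[:, 1] >= 0]
    ident = balign.get_sequence_identity(aln, mode="all")
    return HomologyHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=raw,
        bitscore=bitscore(raw),
        evalue=ev,
        q_interval=(int(qcols.min()), int(qcols.max()) + 1),
        s_interval=(int(scols.min()), int(scols.max()) + 1),
        pct_identity=100.0 * float(ident),
    )


def shared_kmer_pairs(a: dict[str, str], b: dict[str, str] | None = None,
                      k: int = 5, min_shared: int = 8,
                      max_bucket: int = 200) -> set[tuple[str, str]]:
    """Pairs of ids sharing >= min_shared exact k-mers (the seeding filter).

    With b=None, screens unordered pairs within ``a``; otherwise screens
    a-vs-b pairs.  k-mers occurring in more than ``max_bucket`` sequences are
    skipped as low-complexity.
    """
    index: dict[str, set[str]] = defaultdict(set)
    for sid, seq in (b if b is not None else a).items():
        for i in range(len(seq) - k + 1):
            index[seq[i:i + k]].add(sid)
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for qid, seq in a.items():
        seen: dict[str, set[str]] = defaultdict(set)
        for i in range(len(seq) - k + 1):
            word = seq[i:i + k]
            hits = index.get(word)
            if hits is None or len(hits) > max_bucket:
                continue
            for sid in hits:
                if b is None and (sid == qid or sid < qid):
                    continue
                seen[sid].add(word)
        for sid, words in seen.items():
            if len(words) >= min_shared:
                counts[(qid, sid)] = len(words)
    return set(counts)


def all_vs_all(proteins: dict[str, str], evalue_max: float = 0.05,
               k: int = 5, min_shared: int = 8) -> list[HomologyHit]:
    """Significant hits among all unordered pairs of a protein collection."""
    pairs = shared_kmer_pairs(proteins, k=k, min_shared=min_shared)
    hits = []
    for qid, sid in sorted(pairs):
        h = align_proteins(proteins[qid], proteins[sid], qid, sid, evalue_max)
        if h is not None:
            hits.append(h)
    return hits


@dataclass
class GeneFamily:
    """A connected component of the significant-hit graph across genomes."""

    family_id: str
    members: set[tuple[str, str]]  # (genome_id, feature_id)
    label: str | None = None


def split_gid(gid: str) -> tuple[str, str]:
    genome, feat = gid.split("|", 1)
    return genome, feat


def join_gid(genome: str, feat: str) -> str:
    return f"{genome}|{feat}"


def build_families(hits, all_ids=None) -> list[GeneFamily]:
    """Connected components of the significant-hit graph.

    ``all_ids`` (global ids ``genome|feature``) adds singleton families for
    proteins with no significant hit.  family_id is the lexicographically
    smallest member id, making the assignment deterministic.
    """
    g = nx.Graph()
    if all_ids:
        g.add_nodes_from(all_ids)
    for h in hits:
        g.add_edge(h.query_id, h.subject_id)
    fams = []
    for comp in nx.connected_components(g):
        members = {split_gid(gid) for gid in comp}
        fams.append(GeneFamily(family_id=min(comp), members=members))
    fams.sort(key=lambda f: f.family_id)
    return fams


@dataclass
class ClassificationResult:
    """Per-feature category assignment with supporting evidence."""

    categories: dict[tuple[str, str], str] = field(default_factory=dict)
    labels: dict[tuple[str, str], str] = field(default_factory=dict)
    evidence: dict[tuple[str, str], HomologyHit] = field(default_factory=dict)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)
    nm_hits: list[HomologyHit] = field(default_factory=list)
    conflicts: list[dict] = field(default_factory=list)

    def counts(self, genome_id: str) -> dict[str, int]:
        out = {"functional": 0, "plastid_associated": 0, "nORF": 0, "nORFan": 0}
        for (g, _f), cat in self.categories.items():
            if g == genome_id:
                out[cat] += 1
        return out


def classify_orfs(proteomes: dict[str, dict[str, str]],
                  reference_db: dict[str, str],
                  plastid_panel: set[str] | None = None,
                  threshold_evalue: float = 0.05,
                  k: int = 5, min_shared: int = 8) -> ClassificationResult:
    """Classify every ORF of every genome as functional / nORF / nORFan.

    proteomes: genome_id -> {feature_id -> protein}.  reference_db maps a
    functional label (gene name) to a reference protein; plastid_panel is the
    set of labels considered plastid-associated.
    """
    if not proteomes or not reference_db:
        raise ValueError("proteomes and reference database must be non-empty")
    plastid_panel = plastid_panel or set()
    flat = {join_gid(g, f): seq
            for g, prots in proteomes.items() for f, seq in prots.items()}
    # vs labeled functional references
    ref_pairs = shared_kmer_pairs(flat, reference_db, k=k, min_shared=min_shared)
    best_ref: dict[str, HomologyHit] = {}
    for qid, label in sorted(ref_pairs):
        h = align_proteins(flat[qid], reference_db[label], qid, label, threshold_evalue)
        if h is None:
            continue
        cur = best_ref.get(qid)
        if cur is None or (h.evalue, -h.raw_score) < (cur.evalue, -cur.raw_score):
            best_ref[qid] = h
    # among the nucleomorph proteomes themselves
    nm_hits = all_vs_all(flat, evalue_max=threshold_evalue, k=k, min_shared=min_shared)
    cross: dict[str, bool] = defaultdict(bool)
    for h in nm_hits:
        gq, _ = split_gid(h.query_id)
        gs, _ = split_gid(h.subject_id)
        if gq != gs:
            cross[h.query_id] = True
            cross[h.subject_id] = True
    res = ClassificationResult(nm_hits=nm_hits)
    for gid in sorted(flat):
        key = split_gid(gid)
        if gid in best_ref:
            label = best_ref[gid].subject_id
            res.categories[key] = ("plastid_associated" if label in plastid_panel
                                   else "functional")
            res.labels[key] = label
            res.evidence[key] = best_ref[gid]
            res.provenance[key] = "reference"
        elif cross[gid]:
            res.categories[key] = "nORF"
        else:
            res.categories[key] = "nORFan"
    return res


def synteny_transfer_labels(result: ClassificationResult,
                            families: list[GeneFamily],
                            blocks=None) -> ClassificationResult:
    """Propagate functional labels within families to syntenic nORF members.

    A hypothetical member gains the functional label carried by another
    member of its family; when blocks are given, only families represented
    among the anchors of some block are eligible (the label is supported by
    a conserved syntenic position).  Distinct labels within one family are
    flagged as conflicts, not resolved.
    """
    eligible = None
    if blocks is not None:
        eligible = {a.family_id for b in blocks for a in b.anchors}
    for fam in families:
        labels = {result.labels[m] for m in fam.members if result.labels.get(m)}
        if not labels:
            continue
        if len(labels) > 1:
            result.conflicts.append(
                {"family_id": fam.family_id, "labels": sorted(labels)}
            )
            continue
        if eligible is not None and fam.family_id not in eligible:
            continue
        label = labels.pop()
        for m in fam.members:
            if result.categories.get(m) in ("nORF", "nORFan"):
                result.categories[m] = "functional"
                result.labels[m] = label
                result.provenance[m] = "synteny-transferred"
        fam.label = label
    return result


def write_hits_tsv(hits, path) -> None:
    """12-column tabular pairwise format (standard tabular alignment layout)."""
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = h.q_interval
            ss, se = h.s_interval
            alen = max(qe - qs, se - ss)
            nident = round(h.pct_identity / 100.0 * min(qe - qs, se - ss))
            fh.write("\t".join(str(v) for v in [
                h.query_id, h.subject_id, round(h.pct_identity, 2), alen,
                alen - nident, 0, qs + 1, qe, ss + 1, se,
                f"{h.evalue:.2e}", round(h.bitscore, 1)]) + "\n")
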
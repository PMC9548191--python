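"""Cross-genome gene-content accounting.

Presence/absence matrices over curated gene panels (with pseudogene state
superseding absence), Venn partitioning of shared gene families by the
subset of genomes they occupy, and the per-genome overview table (sizes,
GC, gene-class counts, telomere literal).
"""

from __future__ import annotations

from importlib import resources
from itertools import combinations

import pandas as pd

from .degradation import PseudogeneCall
from .genome import Genome, genome_stats
from .homology import ClassificationResult, GeneFamily

PANEL_NAMES = ("plastid_core", "photosynthesis_only", "ccac_curvata_shared",
               "plastid_all")


def load_panel(name: str) -> list[str]:
    """A packaged gene panel (one label per line, '#' comments allowed)."""
    if name not in PANEL_NAMES:
        raise KeyError(f"unknown panel {name!r}; available: {PANEL_NAMES}")
    text = resources.files("nmcomp.panels").joinpath(f"{name}.txt").read_text()
    return [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]


def build_pa_matrix(families: list[GeneFamily],
                    classification: ClassificationResult,
                    pseudogene_calls: list[PseudogeneCall],
                    panel: list[str],
                    genome_ids: list[str],
                    genomes: dict | None = None) -> pd.DataFrame:
    """Presence/absence/pseudogene matrix: one row per panel label.

    present: a feature carries the label (directly or synteny-transferred);
    pseudogene: no intact copy, but a pseudogene call with that label
    targets the genome; absent otherwise.  When ``genomes`` (genome_id ->
    Genome) is given, a label claimed by features at two separate loci of
    one genome (more than one run in gene order) raises a conflict error;
    consecutive fragments of one degraded gene count as a single locus.
    """
    label_feats: dict[str, dict[str, bool]] = {lab: {} for lab in panel}
    for key, lab in classification.labels.items():
        if lab in label_feats:
            label_feats[lab][key[0]] = True
    if genomes is not None:
        orders = {gid: g.cds_order() for gid, g in genomes.items()}
        for lab in panel:
            for gid in genome_ids:
                pos = sorted(
                    orders.get(gid, {}).get(f, (None, -1, None))[1]
                    for (g, f), l in classification.labels.items()
                    if g == gid and l == lab and f in orders.get(gid, {}))
                runs = sum(1 for a, b in zip(pos, pos[1:]) if b - a > 3) + \
                    (1 if pos else 0)
                if runs > 1:
                    raise ValueError(
                        f"panel label {lab!r} maps to {runs} separate loci "
                        f"in genome {gid}")
    pseudo: dict[tuple[str, str], bool] = {}
    for call in pseudogene_calls:
        pseudo[(call.functional_label, call.event.fragmented_genome)] = True
    data = {}
    for lab in panel:
        row = []
        for g in genome_ids:
            if label_feats[lab].get(g):
                row.append("present")
            elif pseudo.get((lab, g)):
                row.append("pseudogene")
            else:
                row.append("absent")
        data[lab] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=genome_ids)


def venn_partition(families: list[GeneFamily], genome_ids: list[str],
                   classification: ClassificationResult | None = None,
                   restrict_to: str | None = "nORF") -> dict[frozenset, int]:
    """Count families by the exact subset of genomes in which they occur.

    restrict_to filters family membership to features of one category
    (None: any member counts).  Every non-empty subset of genomes maps to
    the number of families whose presence set equals it; counts over all
    subsets sum to the number of families considered.
    """
    if not genome_ids:
        raise ValueError("empty genome list")
    gset = set(genome_ids)
    partition: dict[frozenset, int] = {
        frozenset(c): 0
        for r in range(1, len(genome_ids) + 1)
        for c in combinations(sorted(genome_ids), r)
    }
    for fam in families:
        present = set()
        for g, f in fam.members:
            if g not in gset:
                continue
            if restrict_to is not None and classification is not None:
                if classification.categories.get((g, f)) != restrict_to:
                    continue
            present.add(g)
        if present:
            partition[frozenset(present)] += 1
    return partition


def venn_to_json_dict(partition: dict[frozenset, int]) -> dict[str, int]:
    return {",".join(sorted(k)): v for k, v in sorted(
        partition.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))}


def summary_table(genomes: list[Genome],
                  classification: ClassificationResult,
                  telomere_literals: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-genome overview mirroring the standard nucleomorph genome table."""
    rows = []
    for g in genomes:
        st = genome_stats(g)
        counts = classification.counts(g.strain_id)
        kinds = st["n_features_by_kind"]
        row = {
            "genome_id": g.strain_id,
            "photosynthetic": g.photosynthetic,
            "genome_size_bp": st["size_bp"],
        }
        for i, size in enumerate(st["chromosome_sizes"], start=1):
            row[f"chromosome_{i}_bp"] = size
        row.update({
            "gc_percent": round(st["gc"].gc_percent, 2),
            "n_protein_coding": kinds["CDS"],
            "n_trna": kinds["tRNA"],
            "n_rrna": kinds["rRNA"],
            "n_functional": counts["functional"] + counts["plastid_associated"],
            "n_plastid_associated": counts["plastid_associated"],
            "n_norf": counts["nORF"],
            "n_norfan": counts["nORFan"],
            "n_hypothetical": counts["nORF"] + counts["nORFan"],
        })
        if telomere_literals:
            row["telomere"] = telomere_literals.get(g.strain_id, "")
        rows.append(row)
    return pd.DataFrame(rows)
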
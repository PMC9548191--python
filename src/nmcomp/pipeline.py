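"""Convenience drivers wiring the analysis stages together."""

from __future__ import annotations

from .genome import Genome
from .homology import (ClassificationResult, GeneFamily, build_families,
                       classify_orfs, join_gid)


def proteomes(genomes: dict[str, Genome]) -> dict[str, dict[str, str]]:
    """genome_id -> {feature_id -> protein} for all annotated CDS features."""
    out: dict[str, dict[str, str]] = {}
    for gid, g in genomes.items():
        out[gid] = {f.feature_id: f.protein for f in g.cds_features()
                    if f.protein}
    return out


def classify_genomes(genomes: dict[str, Genome], reference_db: dict[str, str],
                     plastid_panel: set[str], threshold_evalue: float = 0.05,
                     ) -> tuple[ClassificationResult, list[GeneFamily]]:
    """All-vs-all classification plus family clustering for a genome set."""
    prots = proteomes(genomes)
    result = classify_orfs(prots, reference_db, plastid_panel,
                           threshold_evalue=threshold_evalue)
    all_ids = [join_gid(g, f) for g, fs in prots.items() for f in fs]
    families = build_families(result.nm_hits, all_ids)
    return result, families
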
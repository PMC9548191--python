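#!/usr/bin/env python
"""Gene-content census: summary table, plastid panel, shared-nORF Venn.

Mirrors the standard nucleomorph overview table (sizes, GC, gene-class
counts, telomere literal per strain), the presence/absence matrix over the
31-gene plastid-associated panel, and the partition of nORF families by
the exact subset of genomes sharing them.  Outputs under results/census/.
"""

import json
import os
import sys

from nmcomp.census import (build_pa_matrix, load_panel, summary_table,
                           venn_partition, venn_to_json_dict)
from nmcomp.degradation import decompose_telomere
from nmcomp.pipeline import classify_genomes
from nmcomp.simulate import SimulationConfig, simulate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "census")


def main():
    res = simulate(SimulationConfig(seed=SEED))
    cls, families = classify_genomes(res.genomes, res.reference_db,
                                     res.plastid_panel)
    os.makedirs(OUT, exist_ok=True)
    gids = sorted(res.genomes)
    tels = {}
    for gid in gids:
        motif = res.config.telomere_motifs[gid]
        tm = decompose_telomere(res.genomes[gid].chromosomes[0], "left",
                                window=len(motif))
        tels[gid] = tm.literal
    table = summary_table([res.genomes[g] for g in gids], cls, tels)
    table.to_csv(os.path.join(OUT, "summary.tsv"), sep="\t", index=False)
    print(table.to_string(index=False))

    pa = build_pa_matrix(families, cls, [], load_panel("plastid_all"), gids,
                         genomes=res.genomes)
    pa.to_csv(os.path.join(OUT, "pa_matrix.tsv"), sep="\t")
    present = (pa == "present").sum()
    print("\nplastid-associated genes present:")
    print(present.to_string())

    part = venn_partition(families, gids, cls, restrict_to="nORF")
    with open(os.path.join(OUT, "venn.json"), "w") as fh:
        json.dump(venn_to_json_dict(part), fh, indent=1)
    print(f"\nnORF families shared by all five strains: "
          f"{part[frozenset(gids)]} of {sum(part.values())}")


if __name__ == "__main__":
    main()
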
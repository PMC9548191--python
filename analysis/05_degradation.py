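#!/usr/bin/env python
"""Genome-degradation readouts: fragmentation, pseudogenes, telomeres.

Scans the family table for 1-vs-k syntenic configurations (one intact gene
matching k >= 2 consecutive smaller ORFs in another genome), types the
disrupting mutation (single-base deletion vs premature stop) for events
whose intact copy has a functional label, and decomposes every chromosome
end into tandem telomere motifs.  Tables under results/degradation/.
"""

import os
import sys

from nmcomp.degradation import (detect_fragmentation, genome_telomeres,
                                type_disruption)
from nmcomp.pipeline import classify_genomes, proteomes
from nmcomp.simulate import SimulationConfig, simulate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "degradation")


def main():
    res = simulate(SimulationConfig(seed=SEED))
    cls, families = classify_genomes(res.genomes, res.reference_db,
                                     res.plastid_panel)
    events = detect_fragmentation(families, res.genomes,
                                  proteomes(res.genomes))
    os.makedirs(OUT, exist_ok=True)
    with open(os.path.join(OUT, "fragmentation.tsv"), "w") as fh:
        fh.write("intact_genome\tintact_feature\tfragmented_genome\tk\t"
                 "coverage\tfragments\n")
        for e in events:
            fh.write(f"{e.intact_genome}\t{e.intact_feature_id}\t"
                     f"{e.fragmented_genome}\t{e.k}\t"
                     f"{e.combined_coverage:.2f}\t"
                     f"{','.join(e.fragment_ids)}\n")
    n_pseudo = 0
    with open(os.path.join(OUT, "pseudogenes.tsv"), "w") as fh:
        fh.write("intact_genome\tlabel\tfragmented_genome\tk\tcoverage\t"
                 "disruption_type\tpositions_aa\n")
        for e in events:
            label = cls.labels.get((e.intact_genome, e.intact_feature_id))
            if not label:
                continue  # fragmentation between hypothetical ORFs: not a
                # pseudogene call, only genes with predicted function qualify
            call = type_disruption(e, res.genomes, label)
            n_pseudo += 1
            fh.write(f"{e.intact_genome}\t{label}\t{e.fragmented_genome}\t"
                     f"{e.k}\t{e.combined_coverage:.2f}\t"
                     f"{call.disruption_type}\t"
                     f"{','.join(map(str, call.disruption_positions))}\n")
    with open(os.path.join(OUT, "telomeres.tsv"), "w") as fh:
        fh.write("genome_id\tchromosome_id\tend\tliteral\n")
        for gid in sorted(res.genomes):
            for tm in genome_telomeres(res.genomes[gid]):
                fh.write(f"{gid}\t{tm.chromosome_id}\t{tm.chromosome_end}\t"
                         f"{tm.literal}\n")
    ks = sorted(e.k for e in events)
    print(f"{len(events)} fragmentation configurations "
          f"(k range {ks[0]}-{ks[-1]})" if events else "no fragmentation")
    print(f"{n_pseudo} pseudogene calls (functional label present)")
    print(f"telomere models for {len(res.genomes)} genomes x 3 chromosomes x 2 ends")


if __name__ == "__main__":
    main()
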
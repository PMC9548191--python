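"""De novo ORF calling on nucleomorph-scale sequences.

Calls all maximal ATG-initiated open reading frames on both strands and all
six frames under the standard genetic code.  An ORF starts at the first ATG
after the previous in-frame stop and runs to the next in-frame stop; ORFs
reaching the end of the sequence without a stop are not reported.  The
calling floor defaults to 50 amino acids, the conventional threshold for
annotating hypothetical nucleomorph ORFs.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

from .genome import Chromosome, revcomp

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = tuple(_TABLE.stop_codons)


def translate(dna: str, code: int = 1) -> str:
    """Standard-table translation; internal stops rendered as ``*``.

    Codons containing N (or anything outside the table) translate to X and
    never match ATG or a stop.  Length must be a multiple of 3.
    """
    if code != 1:
        raise ValueError("only the standard genetic code (table 1) is supported")
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} is not a multiple of 3")
    return "".join(CODON_TO_AA.get(dna[i:i + 3], "X") for i in range(0, len(dna), 3))


@dataclass(frozen=True)
class OrfCall:
    """One called ORF; coordinates are genomic (forward strand, half-open)
    and include the terminal stop codon."""

    chromosome_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str

    @property
    def length_aa(self) -> int:
        return len(self.protein)


def call_orfs(chrom: Chromosome, min_aa: int = 50, code: int = 1) -> list[OrfCall]:
    """All maximal ATG-initiated, stop-terminated ORFs of >= min_aa residues."""
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if code != 1:
        raise ValueError("only the standard genetic code (table 1) is supported")
    seq = chrom.seq
    n = len(seq)
    calls: list[OrfCall] = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            aa = translate(s[frame:frame + 3 * ((n - frame) // 3)])
            start_codon = None  # codon index of current ORF start
            for i, res in enumerate(aa):
                codon = s[frame + 3 * i: frame + 3 * i + 3]
                if res == "*":
                    if start_codon is not None:
                        length = i - start_codon
                        if length >= min_aa:
                            lo = frame + 3 * start_codon
                            hi = frame + 3 * (i + 1)
                            if strand == "-":
                                lo, hi = n - hi, n - lo
                            calls.append(
                                OrfCall(chrom.id, lo, hi, strand, frame,
                                        aa[start_codon:i])
                            )
                    start_codon = None
                elif start_codon is None and codon == "ATG":
                    start_codon = i
    calls = sorted(set(calls), key=lambda c: (c.chromosome_id, c.start, c.end, c.strand))
    return calls


def call_genome_orfs(genome, min_aa: int = 50) -> list[OrfCall]:
    out: list[OrfCall] = []
    for c in genome.chromosomes:
        out.extend(call_orfs(c, min_aa=min_aa))
    return out
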
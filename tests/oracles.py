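"""Independent brute-force oracles shared by the test suite."""

from nmcomp.genome import revcomp


def oracle_orfs(seq: str, min_aa: int):
    """Brute force six-frame ORF enumeration: every (ATG, stop) pair with no
    internal stop, keeping only ATGs that are first after the previous
    in-frame stop.  Returns a set of (start, end, strand) genomic intervals."""
    out = set()
    n = len(seq)
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            codons = [s[i:i + 3] for i in range(frame, n - 2, 3)]
            stops = [i for i, c in enumerate(codons)
                     if c in ("TAA", "TAG", "TGA")]
            prev = -1
            for stop in stops:
                atgs = [i for i in range(prev + 1, stop) if codons[i] == "ATG"]
                if atgs and stop - atgs[0] >= min_aa:
                    lo = frame + 3 * atgs[0]
                    hi = frame + 3 * (stop + 1)
                    if strand == "-":
                        lo, hi = n - hi, n - lo
                    out.add((lo, hi, strand))
                prev = stop
    return out
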
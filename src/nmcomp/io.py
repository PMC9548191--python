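"""Readers and writers for annotated genomes.

GenBank flat files (the format of the deposited nucleomorph records) and
FASTA + GFF3 pairs are supported.  Biopython does the GenBank parsing and
the 1-based-inclusive <-> 0-based-half-open conversion at the boundary;
GFF3 is read through gffutils and written by a plain formatter.  A
round-trip write -> read is the identity on sequences, coordinates, strands
and annotations.
"""

from __future__ import annotations

import os
import urllib.parse

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .genome import (
    Chromosome,
    GeneFeature,
    Genome,
    GenomeValidationError,
    coding_capacity,
    genome_stats,
)

_GB_KINDS = {"CDS", "rRNA", "tRNA"}


class ParseError(ValueError):
    """Raised when an input file does not parse under the named standard."""


def read_genome(path, format: str = "genbank", gff3_path=None, strain_id=None) -> Genome:
    """Read an annotated genome.

    format="genbank": multi-record GenBank flat file, one record per
    chromosome.  format="fasta+gff3": FASTA of chromosome sequences plus a
    GFF3 annotation file (``gff3_path``; defaults to ``path`` with a .gff3
    extension).
    """
    if format == "genbank":
        return read_genbank(path, strain_id=strain_id)
    if format == "fasta+gff3":
        if gff3_path is None:
            gff3_path = os.path.splitext(str(path))[0] + ".gff3"
        return read_fasta_gff3(path, gff3_path, strain_id=strain_id)
    raise ValueError(f"unknown format {format!r}")


def read_genbank(path, strain_id=None) -> Genome:
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # malformed flat file
        raise ParseError(f"{path}: not a parseable GenBank flat file ({exc})") from exc
    if not records:
        raise ParseError(f"{path}: no GenBank records found")
    chroms = []
    organism = None
    photosynthetic = True
    for rec in records:
        organism = organism or rec.annotations.get("organism")
        comment = rec.annotations.get("comment", "")
        if "photosynthetic: no" in comment:
            photosynthetic = False
        feats = []
        for i, f in enumerate(rec.features):
            if f.type not in _GB_KINDS:
                continue
            quals = f.qualifiers
            fid = quals.get("locus_tag", [f"{rec.id}_{f.type}_{i}"])[0]
            if f.location is None:
                raise ParseError(f"{path}: feature {fid} has no location")
            category = quals.get("note", ["category:unclassified"])[0]
            if category.startswith("category:"):
                category = category.split(":", 1)[1]
            else:
                category = "unclassified"
            feats.append(
                GeneFeature(
                    feature_id=fid,
                    chromosome_id=rec.id,
                    start=int(f.location.start),
                    end=int(f.location.end),
                    strand="-" if f.location.strand == -1 else "+",
                    kind=f.type,
                    category=category,
                    product=quals.get("product", [None])[0],
                    protein=quals.get("translation", [None])[0],
                    family_id=quals.get("gene_family", [None])[0],
                )
            )
        try:
            chroms.append(Chromosome(rec.id, str(rec.seq).upper(), feats))
        except GenomeValidationError as exc:
            raise ParseError(f"{path}: record {rec.id}: {exc}") from exc
    return Genome(strain_id or organism or os.path.basename(str(path)), chroms, photosynthetic)


def write_genbank(genome: Genome, path) -> None:
    records = []
    for c in genome.chromosomes:
        rec = SeqRecord(Seq(c.seq), id=c.id, name=c.id[:16], description=genome.strain_id)
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "linear"
        rec.annotations["organism"] = genome.strain_id
        rec.annotations["comment"] = (
            f"photosynthetic: {'yes' if genome.photosynthetic else 'no'}"
        )
        for f in c.features:
            quals = {"locus_tag": [f.feature_id], "note": [f"category:{f.category}"]}
            if f.product:
                quals["product"] = [f.product]
            if f.protein:
                quals["translation"] = [f.protein]
            if f.family_id:
                quals["gene_family"] = [f.family_id]
            rec.features.append(
                SeqFeature(
                    FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1),
                    type=f.kind,
                    qualifiers=quals,
                )
            )
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


def write_fasta(genome: Genome, path) -> None:
    records = [SeqRecord(Seq(c.seq), id=c.id, description=genome.strain_id)
               for c in genome.chromosomes]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in genome.chromosomes:
            fh.write(f"##sequence-region {c.id} 1 {c.length}\n")
        for c in genome.chromosomes:
            for f in c.features:
                attrs = [f"ID={urllib.parse.quote(f.feature_id)}",
                         f"category={f.category}"]
                if f.product:
                    attrs.append(f"product={urllib.parse.quote(f.product)}")
                if f.family_id:
                    attrs.append(f"family={urllib.parse.quote(f.family_id)}")
                fh.write(
                    "\t".join(
                        [c.id, "nmcomp", f.kind, str(f.start + 1), str(f.end),
                         ".", f.strand, ".", ";".join(attrs)]
                    )
                    + "\n"
                )


def read_fasta_gff3(fasta_path, gff3_path, strain_id=None) -> Genome:
    import gffutils

    seqs = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ParseError(f"{fasta_path}: no FASTA records found")
    try:
        db = gffutils.create_db(
            str(gff3_path), ":memory:", from_string=False,
            merge_strategy="create_unique", keep_order=True,
        )
    except Exception as exc:
        raise ParseError(f"{gff3_path}: not a parseable GFF3 file ({exc})") from exc
    feats_by_chrom: dict[str, list[GeneFeature]] = {cid: [] for cid in seqs}
    for f in db.all_features():
        if f.featuretype not in _GB_KINDS:
            continue
        if f.seqid not in seqs:
            raise ParseError(f"{gff3_path}: feature {f.id} on unknown sequence {f.seqid}")
        feats_by_chrom[f.seqid].append(
            GeneFeature(
                feature_id=urllib.parse.unquote(f.id),
                chromosome_id=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand="-" if f.strand == "-" else "+",
                kind=f.featuretype,
                category=f.attributes.get("category", ["unclassified"])[0],
                product=(urllib.parse.unquote(f.attributes["product"][0])
                         if "product" in f.attributes else None),
                family_id=(urllib.parse.unquote(f.attributes["family"][0])
                           if "family" in f.attributes else None),
            )
        )
    chroms = [Chromosome(cid, seq, feats_by_chrom[cid]) for cid, seq in seqs.items()]
    return Genome(strain_id or os.path.basename(str(fasta_path)), chroms)


def write_protein_fasta(genome: Genome, path) -> None:
    """Protein FASTA with ids ``<feature_id> <chrom>:<start>-<end>:<strand>``."""
    with open(path, "w") as fh:
        for c in genome.chromosomes:
            for f in c.features:
                if f.kind == "CDS" and f.protein:
                    fh.write(f">{f.feature_id} {c.id}:{f.start}-{f.end}:{f.strand}\n")
                    fh.write(f.protein + "\n")


def write_stats_tsv(genomes, path) -> None:
    """Per-genome stats table (one row per genome)."""
    cols = ["genome_id", "size_bp", "gc_percent", "n_cds", "n_rrna", "n_trna",
            "functional_pct", "rna_pct", "hypothetical_pct", "intergenic_pct"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for g in genomes:
            st = genome_stats(g)
            cc = coding_capacity(g)
            row = [g.strain_id, st["size_bp"], round(st["gc"].gc_percent, 2),
                   st["n_features_by_kind"]["CDS"], st["n_features_by_kind"]["rRNA"],
                   st["n_features_by_kind"]["tRNA"]] + [
                round(cc[k], 2) for k in cols[6:]
            ]
            fh.write("\t".join(str(v) for v in row) + "\n")
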
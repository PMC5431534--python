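"""Readers and writers for annotated plastomes and trees.

GenBank flat files and FASTA+GFF3 are both 1-based inclusive on disk;
everything in memory is 0-based half-open.  Trees are Newick with branch
lengths, handled by dendropy.
"""

from __future__ import annotations

import os
from typing import Optional

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .genome_model import AnnotatedGenome, GeneFeature

__all__ = [
    "read_genbank",
    "write_genbank",
    "read_fasta_gff3",
    "write_fasta_gff3",
    "read_tree",
    "write_tree",
]

_CLASS_TO_TYPE = {"protein": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
_TYPE_TO_CLASS = {"CDS": "protein", "tRNA": "tRNA", "rRNA": "rRNA"}


def _infer_class(name: str) -> str:
    low = name.lower()
    if low.startswith("trn"):
        return "tRNA"
    if low.startswith("rrn"):
        return "rRNA"
    return "protein"


def read_genbank(path: str) -> AnnotatedGenome:
    """Read one annotated plastome from a GenBank flat file.

    Gene features are taken from ``gene`` records when present, falling back
    to ``CDS``/``tRNA``/``rRNA`` records not already covered by a ``gene`` of
    the same name and position.
    """
    record = SeqIO.read(path, "genbank")
    genes: list[GeneFeature] = []
    seen: set[tuple[str, int]] = set()
    for ftype in ("gene", "CDS", "tRNA", "rRNA"):
        for feat in record.features:
            if feat.type != ftype:
                continue
            quals = feat.qualifiers
            name = (quals.get("gene") or quals.get("locus_tag") or [None])[0]
            if name is None:
                continue
            start = int(feat.location.start)
            if (name, start) in seen:
                continue
            seen.add((name, start))
            segments = [(int(p.start), int(p.end)) for p in feat.location.parts]
            strand = "-" if feat.location.strand == -1 else "+"
            fclass = _TYPE_TO_CLASS.get(ftype, _infer_class(name))
            genes.append(GeneFeature(name, strand, sorted(segments), fclass))
    return AnnotatedGenome(record.id or record.name, str(record.seq).upper(), genes)


def write_genbank(genome: AnnotatedGenome, path: str) -> None:
    """Write an annotated plastome as a GenBank flat file (circular DNA)."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16].replace(" ", "_"),
        description="synthetic plastome" if genome.genes else "",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for g in genome.genes:
        strand = -1 if g.strand == "-" else 1
        parts = [SimpleLocation(s, e, strand) for s, e in g.segments]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        record.features.append(
            SeqFeature(loc, type="gene", qualifiers={"gene": [g.name]})
        )
        record.features.append(
            SeqFeature(
                loc,
                type=_CLASS_TO_TYPE[g.feature_class],
                qualifiers={"gene": [g.name]},
            )
        )
    SeqIO.write([record], path, "genbank")


def write_fasta_gff3(genome: AnnotatedGenome, fasta_path: str, gff_path: str) -> None:
    """Write sequence as FASTA and annotations as GFF3 (gene + exon rows)."""
    record = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    SeqIO.write([record], fasta_path, "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome.sequence)}\n")
        for k, g in enumerate(genome.genes):
            gid = f"gene{k}"
            attrs = f"ID={gid};Name={g.name};gene_class={g.feature_class}"
            fh.write(
                f"{genome.id}\tplastocomp\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for m, (s, e) in enumerate(g.segments):
                fh.write(
                    f"{genome.id}\tplastocomp\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tID={gid}.exon{m};Parent={gid}\n"
                )


def read_fasta_gff3(fasta_path: str, gff_path: str) -> AnnotatedGenome:
    """Read a plastome from a FASTA sequence plus GFF3 annotations."""
    import gffutils

    record = SeqIO.read(fasta_path, "fasta")
    db = gffutils.create_db(
        gff_path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneFeature] = []
    for feat in db.features_of_type("gene", order_by="start"):
        name = feat.attributes.get("Name", [feat.id])[0]
        fclass = feat.attributes.get("gene_class", [_infer_class(name)])[0]
        exons = list(db.children(feat, featuretype="exon", order_by="start"))
        if exons:
            segments = [(e.start - 1, e.end) for e in exons]
        else:
            segments = [(feat.start - 1, feat.end)]
        strand = "-" if feat.strand == "-" else "+"
        genes.append(GeneFeature(name, strand, segments, fclass))
    return AnnotatedGenome(record.id, str(record.seq).upper(), genes)


def read_tree(path: str) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths."""
    tree = dendropy.Tree.get(path=path, schema="newick",
                             preserve_underscores=True)
    return tree


def write_tree(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", unquoted_underscores=True)
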
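"""Readers and writers for the standard formats the pipeline consumes.

FASTA via Biopython, GFF3 via gffutils, BED12 by direct parsing (the format
is 12 tab-separated fields), VCF via cyvcf2. VCF positions are 1-based and
converted to the internal 0-based convention only at this boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .variant_effects import Exon, GeneModel, Transcript, Variant


def load_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an in-memory {contig: sequence} map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, contigs: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_models_gff3(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        transcripts = []
        for tx in db.children(gene, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = [
                Exon(contig=ex.seqid, start=ex.start - 1, end=ex.end)
                for ex in db.children(tx, featuretype="exon", order_by="start")
            ]
            if exons:
                transcripts.append(Transcript(transcript_id=tx.id, exons=tuple(exons)))
        if transcripts:
            models.append(
                GeneModel(gene_id=gene.id, strand=gene.strand, transcripts=tuple(transcripts))
            )
    return models


def write_gff3(path, models: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            all_exons = [e for tx in gm.transcripts for e in tx.exons]
            contig = all_exons[0].contig
            start = min(e.start for e in all_exons) + 1
            end = max(e.end for e in all_exons)
            fh.write(
                f"{contig}\tspliceinfo\tgene\t{start}\t{end}\t.\t{gm.strand}\t.\t"
                f"ID={gm.gene_id}\n"
            )
            for tx in gm.transcripts:
                ts = min(e.start for e in tx.exons) + 1
                te = max(e.end for e in tx.exons)
                fh.write(
                    f"{contig}\tspliceinfo\tmRNA\t{ts}\t{te}\t.\t{gm.strand}\t.\t"
                    f"ID={tx.transcript_id};Parent={gm.gene_id}\n"
                )
                for i, ex in enumerate(tx.exons, 1):
                    fh.write(
                        f"{contig}\tspliceinfo\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{gm.strand}\t.\tID={tx.transcript_id}.e{i};"
                        f"Parent={tx.transcript_id}\n"
                    )


def read_gene_models_bed12(path) -> list[GeneModel]:
    """One transcript per BED12 line; gene id taken from the name field."""
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            contig, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                Exon(contig=contig, start=chrom_start + st, end=chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            models.append(
                GeneModel(
                    gene_id=name,
                    strand=strand,
                    transcripts=(Transcript(transcript_id=name, exons=exons),),
                )
            )
    return models


def read_variants_vcf(path) -> list[Variant]:
    """Read single-nucleotide variants; HET INFO key (if present) supplies
    average heterozygosity. Multi-allelic records yield one Variant per alt."""
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            if len(rec.REF) != 1 or len(alt) != 1:
                continue
            het = rec.INFO.get("HET")
            out.append(
                Variant(
                    contig=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    rsid=rec.ID,
                    het=float(het) if het is not None else None,
                )
            )
    return out


def write_vcf(path, variants: Iterable[Variant], contigs: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=HET,Number=1,Type=Float,Description="Average heterozygosity">\n')
        if contigs:
            for name, seq in contigs.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = f"HET={v.het}" if v.het is not None else "."
            fh.write(
                f"{v.contig}\t{v.pos}\t{v.rsid or '.'}\t{v.ref}\t{v.alt}\t.\t.\t{info}\n"
            )
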
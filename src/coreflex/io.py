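"""Readers and writers for the plain-text formats the pipeline exchanges.

Per-genome protein and CDS FASTA (record id = gene_id), a gene-coordinate
TSV, the mutation table TSV, and the tidy per-stage output tables.  All
tables are tab-separated with a header row; missing values are written as
"NA".
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pangenome import CoreGenomePartition, GeneModel, GenomeAnnotation, OrthologGroup

NA = "NA"

GENE_TABLE_COLUMNS = ["gene_id", "genome_id", "contig", "start", "end", "strand"]


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    seqs = [SeqRecord(Seq(s), id=rid, description="") for rid, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(annotation: GenomeAnnotation, outdir: str | Path) -> None:
    """Emit <genome>.faa, <genome>.fna and <genome>_genes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gid = annotation.genome_id
    genes = dict(sorted(annotation.genes.items()))
    write_fasta({g: m.aa_seq for g, m in genes.items()}, outdir / f"{gid}.faa")
    write_fasta({g: m.nt_seq for g, m in genes.items()}, outdir / f"{gid}.fna")
    rows = [
        {
            "gene_id": m.gene_id,
            "genome_id": m.genome_id,
            "contig": m.contig,
            "start": m.start,
            "end": m.end,
            "strand": m.strand,
        }
        for m in genes.values()
    ]
    write_tsv(pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS), outdir / f"{gid}_genes.tsv")


def read_genome(genome_id: str, indir: str | Path) -> GenomeAnnotation:
    """Rebuild a GenomeAnnotation from the files write_genome emitted."""
    indir = Path(indir)
    aa = read_fasta(indir / f"{genome_id}.faa")
    nt = read_fasta(indir / f"{genome_id}.fna")
    coords = read_tsv(indir / f"{genome_id}_genes.tsv")
    annot = GenomeAnnotation(genome_id=genome_id)
    for row in coords.itertuples(index=False):
        annot.add(
            GeneModel(
                gene_id=row.gene_id,
                genome_id=row.genome_id,
                contig=row.contig,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                nt_seq=nt[row.gene_id],
                aa_seq=aa[row.gene_id],
            )
        )
    return annot


def write_partition(partition: CoreGenomePartition, path: str | Path) -> None:
    rows = [
        {"gene_id": g, "compartment": "core"} for g in sorted(partition.core_gene_ids)
    ] + [
        {"gene_id": g, "compartment": "flexible"}
        for g in sorted(partition.flexible_gene_ids)
    ]
    write_tsv(pd.DataFrame(rows), path)


def write_ortholog_groups(groups: list[OrthologGroup], path: str | Path) -> None:
    rows = [
        {"family_id": grp.family_id, "genome_id": g, "gene_id": gene}
        for grp in groups
        for g, gene in grp.members
    ]
    write_tsv(pd.DataFrame(rows, columns=["family_id", "genome_id", "gene_id"]), path)
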
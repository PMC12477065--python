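"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython, VCF reading through cyvcf2; GMT and the
simple TSV tables are thin pandas wrappers. VCF output is written directly
as minimal VCF 4.2 text (variants here live in transcript coordinates, so
CHROM is a transcript id and no reference index is involved).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path: str | os.PathLike) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_matrix_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature x sample matrix TSV (first column = feature ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=True)


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=TP,Number=1,Type=String,Description="Planted variant type">\n'
)


def write_vcf(
    variants: Iterable[tuple[str, int, str, str, str]],
    contigs: Mapping[str, int],
    path: str | os.PathLike,
) -> None:
    """Write (chrom, pos0, ref, alt, info_type) tuples as minimal VCF 4.2.

    ``pos0`` is 0-based; the file is written 1-based per the VCF standard.
    """
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        rows = sorted(variants, key=lambda v: (v[0], v[1], v[2], v[3]))
        for chrom, pos0, ref, alt, vtype in rows:
            fh.write(f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\tTP={vtype}\n")


def read_vcf(path: str | os.PathLike) -> list[tuple[str, int, str, str]]:
    """Read a VCF into (chrom, pos0, ref, alt) tuples (0-based positions)."""
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            out.append((rec.CHROM, rec.POS - 1, rec.REF, alt))
    return out
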
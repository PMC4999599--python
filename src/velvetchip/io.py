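"""Readers and writers for the plain-text formats the pipeline exchanges.

Internally everything is 0-based, half-open (BED convention); GFF3 is
converted to and from its native 1-based inclusive coordinates at the
boundary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .consensus import GeneModel


def write_fasta(genome: Dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: Sequence[GeneModel], path: str | Path, source: str = "velvetchip") -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            handle.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_gff3(path: str | Path, feature_type: str = "gene") -> List[GeneModel]:
    genes: List[GeneModel] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if fields[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", f"{feature_type}_{lineno}")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6],
                )
            )
    return genes


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_ground_truth(truth, path: str | Path) -> None:
    payload = {
        "site_positions": {c: list(map(int, v)) for c, v in truth.site_positions.items()},
        "motif_positions": [
            {"chrom": c, "center": int(p), "strand": s} for c, p, s in truth.motif_positions
        ],
        "dependent_genes": sorted(truth.dependent_genes),
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=1, sort_keys=True)
        handle.write("\n")
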
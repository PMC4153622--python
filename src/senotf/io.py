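"""Readers and writers for the pipeline's plain-text formats.

TSV writers prepend a ``# config_hash=...`` comment line (pandas-compatible)
when a hash is supplied; readers skip ``#`` comments.  Promoter FASTA files
carry bare gene ids with no description.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .de import ExpressionMatrix
from .motifs import IUPACMotif, PromoterCollection
from .quant import CultureLog


def write_tsv(df: pd.DataFrame, path: str | Path, config_hash: str | None = None,
              index: bool = False) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_promoters(promoters: PromoterCollection, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="")
        for gene_id, seq in promoters.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_promoters(path: str | Path) -> PromoterCollection:
    return PromoterCollection(
        {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    )


def write_expression(
    matrix: ExpressionMatrix,
    matrix_path: str | Path,
    samples_path: str | Path,
    config_hash: str | None = None,
) -> None:
    write_tsv(matrix.values.rename_axis("gene_id"), matrix_path, config_hash, index=True)
    write_tsv(matrix.samples.rename_axis("sample_id"), samples_path, config_hash, index=True)


def read_expression(matrix_path: str | Path, samples_path: str | Path) -> ExpressionMatrix:
    values = read_tsv(matrix_path, index_col="gene_id")
    samples = read_tsv(samples_path, index_col="sample_id")
    return ExpressionMatrix(values, samples)


def write_motifs(motifs: Sequence[IUPACMotif], path: str | Path,
                 config_hash: str | None = None) -> None:
    df = pd.DataFrame(
        [(m.tf_gene_id, m.pattern, m.variant_count) for m in motifs],
        columns=["tf_gene_id", "pattern", "variant_count"],
    )
    write_tsv(df, path, config_hash)


def read_motifs(path: str | Path) -> list[IUPACMotif]:
    df = read_tsv(path)
    return [IUPACMotif(row.tf_gene_id, row.pattern) for row in df.itertuples()]


def read_culture_log(path: str | Path, initial_pd: float = 0.0) -> CultureLog:
    df = read_tsv(path)
    return CultureLog(
        [(str(r.passage), float(r.n_inoculated), float(r.n_final))
         for r in df.itertuples()],
        initial_pd=initial_pd,
    )
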
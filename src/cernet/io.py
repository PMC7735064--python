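"""Readers and writers for the pipeline's plain-text interchange formats.

Expression and annotation tables travel as TSV; single-cell counts as a 10x
style MTX triplet (matrix.mtx + barcodes.tsv + features.tsv) or dense TSV;
sequences as FASTA (via Biopython); networks as GraphML (via networkx);
truth and run summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from anndata import AnnData
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as spio
from scipy.sparse import csr_matrix

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_groups_tsv",
    "read_fasta",
    "write_fasta",
    "read_mtx_dir",
    "write_mtx_dir",
    "write_json",
]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Features x samples TSV with a header of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate feature ids in expression table")
    return df


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_groups_tsv(path: str | Path) -> pd.Series:
    """Two-column TSV sample<TAB>group -> Series."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("group")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_mtx_dir(directory: str | Path) -> AnnData:
    """10x-style triplet: matrix.mtx (genes x cells), barcodes.tsv, features.tsv."""
    d = Path(directory)
    m = spio.mmread(d / "matrix.mtx").tocsr()
    barcodes = (d / "barcodes.tsv").read_text().split()
    features = (d / "features.tsv").read_text().split()
    if m.shape != (len(features), len(barcodes)):
        raise ValueError("matrix dimensions do not match barcodes/features")
    adata = AnnData(X=m.T.toarray().astype(float))
    adata.obs_names = barcodes
    adata.var_names = features
    return adata


def write_mtx_dir(counts: pd.DataFrame, directory: str | Path) -> None:
    """Write a genes x cells count table as an MTX triplet."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(d / "matrix.mtx", csr_matrix(counts.to_numpy()))
    (d / "barcodes.tsv").write_text("\n".join(counts.columns) + "\n")
    (d / "features.tsv").write_text("\n".join(counts.index) + "\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
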
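"""Bundled reference tables.

Small plain-text transcriptions of published result tables from the Down
syndrome fetal-hippocampus circRNA study that this package's pipeline
re-implements: the top-20 up/downregulated circRNAs (with chromosome,
parent-gene symbol, adjusted p and log2 fold change), the four DS-associated
miRNAs with their 20 interacting circRNAs each, and the 47-gene AlzData CFG
evidence table (see :mod:`cernet.cfg`).

Numeric columns in the circRNA table preserve the published typography
(U+2212 minus signs); loaders normalise them to floats.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

__all__ = ["load_top_de_circrnas", "load_mirna_circrna_table"]


def _data_path(name: str):
    return importlib.resources.files("cernet") / "data" / name


def load_top_de_circrnas() -> pd.DataFrame:
    """Top-20 upregulated and top-20 downregulated circRNAs.

    Columns: probe, chromosome, parent_gene, p_adj, log2fc.
    """
    with importlib.resources.as_file(_data_path("ds_top_de_circrnas.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    df.columns = ["probe", "chromosome", "parent_gene", "p_adj", "log2fc"]
    for col in ("p_adj", "log2fc"):
        df[col] = df[col].str.replace("−", "-", regex=False).astype(float)
    return df


def load_mirna_circrna_table() -> pd.DataFrame:
    """DS-associated miRNAs and their interacting circRNAs (long format).

    Columns: mirna, circrna — one row per published interaction.
    """
    with importlib.resources.as_file(
        _data_path("ds_mirna_circrna_interactions.tsv")
    ) as p:
        df = pd.read_csv(p, sep="\t")
    df.columns = ["mirna", "circrna"]
    return df
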
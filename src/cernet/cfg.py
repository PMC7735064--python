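"""Convergent functional genomics (CFG) evidence scoring.

The CFG score summarises, per gene, how many independent lines of evidence
link it to Alzheimer-type pathology in the AlzData resource.  Five binary
indicators are summed (score range 0-5):

1. the gene's expression is under control of an AD genetic variant
   (non-zero eQTL count),
2. it carries GWAS support (non-zero GWAS hit count),
3. its protein physically interacts with at least one of the core AD
   proteins APP, PSEN1, PSEN2, APOE or MAPT,
4. it is differentially expressed in AD mouse models before pathology
   emerges (early DEG = yes),
5. its expression correlates significantly with pathology load in either
   the amyloid-beta or the tau mouse line (at least one asterisk).

Missing evidence ("NA", dashes) never contributes.  A transcription of the
published 47-gene evidence table for the Down-syndrome core ceRNA network
targets ships with the package (:func:`load_published_evidence`) and the
recomputed scores reproduce its printed CFG column exactly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "AD_CORE_GENES",
    "EvidenceRecord",
    "CFGScore",
    "cfg_score",
    "parse_evidence_table",
    "score_table",
    "load_published_evidence",
    "verify_published_scores",
]

AD_CORE_GENES = frozenset({"APP", "PSEN1", "PSEN2", "APOE", "MAPT"})

_MISSING = {"", "-", "–", "−", "NA", "na", "NaN", "nan", "None"}
_MARKS = {"ns", "*", "**", "***"}


@dataclass
class EvidenceRecord:
    """One gene's evidence row; ``None`` means the cell was missing."""

    gene: str
    eqtl_count: int | None = None
    gwas_count: int | None = None
    ppi_partners: frozenset[str] | None = None
    early_deg: str | None = None  # "yes" / "no" / None
    abeta_cor: tuple[float, str] | None = None  # (r, mark)
    tau_cor: tuple[float, str] | None = None
    printed_cfg: int | None = None  # retained for verification only


@dataclass
class CFGScore:
    gene: str
    score: int
    indicators: dict[str, bool] = field(default_factory=dict)


def cfg_score(record: EvidenceRecord) -> CFGScore:
    """Additive five-indicator CFG score; missing evidence scores nothing."""
    ind = {
        "eqtl": bool(record.eqtl_count),
        "gwas": bool(record.gwas_count),
        "ppi": bool(record.ppi_partners),
        "early_deg": record.early_deg == "yes",
        "pathology_cor": any(
            c is not None and c[1] in {"*", "**", "***"}
            for c in (record.abeta_cor, record.tau_cor)
        ),
    }
    return CFGScore(gene=record.gene, score=sum(ind.values()), indicators=ind)


def _clean(cell) -> str:
    s = "" if cell is None or (isinstance(cell, float) and pd.isna(cell)) else str(cell)
    return s.strip()


def _parse_count(cell, where: str) -> int | None:
    s = _clean(cell)
    if s in _MISSING:
        return None
    try:
        v = int(float(s))
    except ValueError as exc:
        raise ValueError(f"unparseable count {cell!r} in {where}") from exc
    if v < 0:
        raise ValueError(f"negative count {cell!r} in {where}")
    return v


def _parse_ppi(cell, where: str) -> frozenset[str] | None:
    s = _clean(cell)
    if s in _MISSING:
        return None
    partners = frozenset(p.strip() for p in s.split(",") if p.strip())
    unknown = partners - AD_CORE_GENES
    if unknown:
        raise ValueError(f"unknown PPI partner(s) {sorted(unknown)} in {where}")
    return partners if partners else None


def _parse_early(cell, where: str) -> str | None:
    s = _clean(cell)
    if s in _MISSING:
        return None
    low = s.lower()
    if low in ("yes", "no"):
        return low
    raise ValueError(f"unparseable early-DEG value {cell!r} in {where}")


def _parse_cor(cell, where: str) -> tuple[float, str] | None:
    s = _clean(cell)
    if s in _MISSING:
        return None
    parts = [p.strip() for p in s.split(",")]
    if len(parts) != 2 or parts[1] not in _MARKS:
        raise ValueError(f"unparseable pathology-correlation cell {cell!r} in {where}")
    # the printed tables mix U+2212 and ASCII hyphens for the minus sign
    num = parts[0].replace("−", "-").replace("–", "-")
    try:
        r = float(num)
    except ValueError as exc:
        raise ValueError(f"unparseable correlation value {cell!r} in {where}") from exc
    return r, parts[1]


_COLUMNS = {
    "gene": ["gene"],
    "eqtl": ["eqtl"],
    "gwas": ["gwas"],
    "ppi": ["ppi"],
    "early_deg": ["early_deg", "earlydeg"],
    "abeta": ["pathology cor (abeta)", "abeta", "pathology_cor_abeta"],
    "tau": ["pathology cor (tau)", "tau", "pathology_cor_tau"],
    "cfg": ["cfg"],
}


def _find_col(df: pd.DataFrame, key: str, required: bool = True) -> str | None:
    lowered = {c.lower().strip(): c for c in df.columns}
    for alias in _COLUMNS[key]:
        if alias in lowered:
            return lowered[alias]
    if required:
        raise ValueError(f"evidence table is missing a {key!r} column")
    return None


def parse_evidence_table(path_or_df: str | Path | pd.DataFrame) -> list[EvidenceRecord]:
    """Parse a TSV evidence table into typed records.

    Dialect: "-", "–" and "NA" mark missing cells; pathology correlations are
    "value, mark" with mark in {ns, *, **, ***}; PPI partners are a
    comma-separated subset of APP/PSEN1/PSEN2/APOE/MAPT.  A printed CFG
    column, if present, is retained for verification only.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t", dtype=str, keep_default_na=False)
    cols = {k: _find_col(df, k, required=k != "cfg") for k in _COLUMNS}
    records = []
    for i, row in df.iterrows():
        where = f"row {i + 2}"  # 1-based with header line
        gene = _clean(row[cols["gene"]])
        if not gene:
            raise ValueError(f"missing gene symbol in {where}")
        printed = None
        if cols["cfg"] is not None:
            printed = _parse_count(row[cols["cfg"]], where)
        records.append(
            EvidenceRecord(
                gene=gene,
                eqtl_count=_parse_count(row[cols["eqtl"]], where),
                gwas_count=_parse_count(row[cols["gwas"]], where),
                ppi_partners=_parse_ppi(row[cols["ppi"]], where),
                early_deg=_parse_early(row[cols["early_deg"]], where),
                abeta_cor=_parse_cor(row[cols["abeta"]], where),
                tau_cor=_parse_cor(row[cols["tau"]], where),
                printed_cfg=printed,
            )
        )
    return records


def score_table(records: list[EvidenceRecord]) -> pd.DataFrame:
    """Score every record; returns gene, score, indicator breakdown."""
    rows = []
    for rec in records:
        s = cfg_score(rec)
        rows.append({"gene": s.gene, "cfg": s.score, **s.indicators})
    return pd.DataFrame(rows)


def load_published_evidence() -> pd.DataFrame:
    """The bundled 47-gene AlzData evidence table (published transcription)."""
    ref = importlib.resources.files("cernet") / "data" / "alzdata_cfg_evidence.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)


def verify_published_scores() -> pd.DataFrame:
    """Recompute CFG for the bundled table and compare to its printed column.

    Returns the per-gene comparison; raises if any score disagrees.
    """
    records = parse_evidence_table(load_published_evidence())
    out = score_table(records)
    out["printed"] = [r.printed_cfg for r in records]
    bad = out[out["cfg"] != out["printed"]]
    if len(bad):
        raise AssertionError(f"CFG mismatch for {bad['gene'].tolist()}")
    return out
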
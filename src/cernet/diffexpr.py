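"""Two-group differential expression on log2-scale intensities.

The case/control contrast uses a per-feature Welch two-sample t-test on
log2 values with Benjamini-Hochberg adjustment across all tested features.
Significance follows the strict thresholds |log2FC| > 1.0 and adjusted
p < 0.05 used throughout the pipeline.  Also provides the descriptive
summaries (category, chromosome and parent-gene breakdowns, top-n tables)
and the 2^-ddCt relative-expression statistic used for qRT-PCR validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "differential_test",
    "filter_de",
    "summarize_de",
    "SummaryReport",
    "relative_expression_ddct",
]


def _check_groups(sample_ids, groups: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    g = groups.reindex(sample_ids)
    if g.isna().any():
        missing = list(g.index[g.isna()])
        raise ValueError(f"samples without group label: {missing}")
    bad = set(g.unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"group labels must be 'case'/'control', got {sorted(bad)}")
    case = (g == "case").to_numpy()
    ctrl = (g == "control").to_numpy()
    if case.sum() < 2 or ctrl.sum() < 2:
        raise ValueError("need at least two samples per group")
    return case, ctrl


def differential_test(
    matrix: pd.DataFrame,
    groups: pd.Series,
    *,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature Welch t-test of case vs control on a log2-scale matrix.

    Parameters
    ----------
    matrix
        features x samples, log2 intensities (or log-normalised counts).
    groups
        sample id -> "case" / "control".
    lfc_min, alpha
        thresholds used only to set the ``direction`` flag
        (strict inequalities: |log2fc| > lfc_min and p_adj < alpha).

    Returns a DataFrame indexed by feature with columns ``log2fc`` (case
    minus control mean), ``p_raw``, ``p_adj`` (BH over all features),
    ``direction`` in {up, down, ns} and ``constant`` (flagging features with
    zero variance in both groups, whose p is set to 1 by convention).
    """
    case, ctrl = _check_groups(matrix.columns, groups)
    x = matrix.to_numpy(dtype=float)
    a, b = x[:, case], x[:, ctrl]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p_raw = stats.ttest_ind(a, b, axis=1, equal_var=False)
    constant = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    p_raw = np.where(np.isnan(p_raw) | constant, 1.0, p_raw)
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    res = pd.DataFrame(
        {"log2fc": log2fc, "p_raw": p_raw, "p_adj": p_adj, "constant": constant},
        index=matrix.index,
    )
    sig = (res["log2fc"].abs() > lfc_min) & (res["p_adj"] < alpha)
    res["direction"] = np.where(~sig, "ns", np.where(res["log2fc"] > 0, "up", "down"))
    return res[["log2fc", "p_raw", "p_adj", "direction", "constant"]]


def filter_de(
    records: pd.DataFrame,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Keep features with |log2fc| > lfc_min AND p_adj < alpha (both strict).

    Returns the significant subset with ``direction`` recomputed at the
    given thresholds (up/down partition).
    """
    req = {"log2fc", "p_adj"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must carry columns {sorted(req)}")
    keep = (records["log2fc"].abs() > lfc_min) & (records["p_adj"] < alpha)
    out = records.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


@dataclass
class SummaryReport:
    """Descriptive breakdown of a significant DE set."""

    n_up: int
    n_down: int
    category_counts: pd.Series
    chromosome_counts: pd.DataFrame  # chromosome x {up, down}
    parent_gene_groups: pd.DataFrame  # parent_gene, direction, n_members
    top_table: pd.DataFrame  # top-n by |log2fc| per direction
    unknown_features: list[str] = field(default_factory=list)


def summarize_de(
    significant: pd.DataFrame,
    annotation: pd.DataFrame,
    *,
    top_n: int = 20,
) -> SummaryReport:
    """Summarise a significant DE table against a feature annotation.

    ``annotation`` is indexed by feature id with columns ``chromosome``,
    ``parent_gene`` and ``category``.  Unannotated features are tallied
    under "unknown" with a warning.  Top-n tables per direction rank by
    |log2fc| descending with ties broken by smaller p_adj then feature id.
    """
    sig = significant.copy()
    if "direction" not in sig.columns:
        sig["direction"] = np.where(sig["log2fc"] > 0, "up", "down")
    ann = annotation.reindex(sig.index)
    unknown = list(sig.index[ann["parent_gene"].isna()])
    if unknown:
        warnings.warn(f"{len(unknown)} significant feature(s) lack annotation")
    for col in ("chromosome", "parent_gene", "category"):
        if col in ann.columns:
            ann[col] = ann[col].fillna("unknown")
    df = sig.join(ann)

    chrom = (
        df.groupby(["chromosome", "direction"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["up", "down"], fill_value=0)
    )
    groups = (
        df.groupby(["parent_gene", "direction"], observed=True)
        .size()
        .rename("n_members")
        .reset_index()
        .sort_values(["n_members", "parent_gene"], ascending=[False, True])
        .reset_index(drop=True)
    )
    cat = df["category"].value_counts() if "category" in df.columns else pd.Series(dtype=int)

    tops = []
    for direction in ("up", "down"):
        sub = df[df["direction"] == direction].copy()
        sub["_abs"] = sub["log2fc"].abs()
        sub = sub.sort_values(
            ["_abs", "p_adj"] if "p_adj" in sub.columns else ["_abs"],
            ascending=[False, True] if "p_adj" in sub.columns else [False],
            kind="mergesort",
        )
        # stable sort + index tie-break for exact |log2fc| and p_adj ties
        sub = sub.head(top_n).drop(columns="_abs")
        tops.append(sub)
    top_table = pd.concat(tops)

    return SummaryReport(
        n_up=int((df["direction"] == "up").sum()),
        n_down=int((df["direction"] == "down").sum()),
        category_counts=cat,
        chromosome_counts=chrom,
        parent_gene_groups=groups,
        top_table=top_table,
        unknown_features=unknown,
    )


def relative_expression_ddct(
    ct_target: pd.Series,
    ct_reference: pd.Series,
    groups: pd.Series,
) -> dict:
    """Relative expression by the 2^-ddCt method with a Student t-test.

    dCt = Ct_target - Ct_reference per sample; ddCt subtracts the mean
    control dCt; fold = 2^-ddCt.  Samples missing the reference Ct are
    dropped with a warning; with fewer than two samples in either group the
    t-test p-value is reported as NaN.

    Returns ``{"fold": per-sample Series, "mean_fold_case": float,
    "mean_fold_control": float, "p_value": float}``.
    """
    missing = ct_target.index[ct_reference.reindex(ct_target.index).isna()]
    if len(missing):
        warnings.warn(f"dropping samples without reference Ct: {list(missing)}")
    samples = ct_target.index.difference(missing)
    dct = ct_target.loc[samples] - ct_reference.loc[samples]
    g = groups.reindex(samples)
    ctrl_dct = dct[g == "control"]
    if ctrl_dct.empty:
        raise ValueError("no control samples with complete Ct values")
    ddct = dct - ctrl_dct.mean()
    fold = 2.0 ** (-ddct)
    case_dct = dct[g == "case"]
    if len(case_dct) >= 2 and len(ctrl_dct) >= 2:
        if case_dct.std() == 0 and ctrl_dct.std() == 0:
            # degenerate: identical within groups; equal means -> no evidence
            p = 1.0 if case_dct.mean() == ctrl_dct.mean() else 0.0
        else:
            _, p = stats.ttest_ind(case_dct, ctrl_dct, equal_var=True)
            p = float(p)
    else:
        p = float("nan")
    return {
        "fold": fold,
        "mean_fold_case": float(fold[g == "case"].mean()),
        "mean_fold_control": float(fold[g == "control"].mean()),
        "p_value": p,
    }
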
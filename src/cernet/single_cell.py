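"""Single-cell QC, normalisation, clustering and module-trait correlation.

The QC gates follow the strict published thresholds: cells are kept iff
they detect more than 800 and fewer than 7,000 genes and their
mitochondrial UMI fraction is below 15%; genes are then kept iff detected
in at least 30 retained cells.  Counts are depth-normalised to 10,000 per
cell and log1p-transformed; the top 3,000 dispersion-ranked highly variable
genes feed PCA, a shared-nearest-neighbour graph and Leiden community
detection with a fixed seed.  Per-cluster downsampling keeps the first 40
barcodes (lexicographic) within each (sample, cluster).  Cell types are
assigned per cluster from marker-gene score margins, and module eigengenes
computed over cells are correlated against one-hot cell-type and
gestational-week indicators (cell-type-specific iff max |r| > 0.6;
developmentally stable iff all gestational-week |r| < 0.3).

The canonical in-memory container is :class:`anndata.AnnData`
(cells x genes); :func:`from_counts` adapts a genes x cells count table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scanpy as sc
from anndata import AnnData

__all__ = [
    "QCThresholds",
    "QCReport",
    "from_counts",
    "qc_filter",
    "normalize_and_hvg",
    "cluster_cells",
    "downsample_per_cluster",
    "annotate_cell_types",
    "module_celltype_correlation",
]


@dataclass(frozen=True)
class QCThresholds:
    """Strict (exclusive) QC bounds."""

    min_genes: int = 800
    max_genes: int = 7000
    min_cells_per_gene: int = 30
    max_mito_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be below max_genes")


@dataclass
class QCReport:
    n_input_cells: int
    n_retained_cells: int
    n_input_genes: int
    n_retained_genes: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    removed_cells: list[str] = field(default_factory=list)


def from_counts(
    counts: pd.DataFrame,
    obs: pd.DataFrame | None = None,
    mito_genes: list[str] | None = None,
) -> AnnData:
    """Build an AnnData from a genes x cells count table.

    Mitochondrial genes are flagged from ``mito_genes`` if given, else by
    the ``MT-`` name prefix.
    """
    adata = AnnData(
        X=counts.to_numpy(dtype=np.float64).T,
        obs=obs.loc[counts.columns].copy() if obs is not None else pd.DataFrame(index=counts.columns),
        var=pd.DataFrame(index=counts.index),
    )
    if mito_genes is not None:
        adata.var["mito"] = adata.var_names.isin(mito_genes)
    else:
        adata.var["mito"] = adata.var_names.str.upper().str.startswith("MT-")
    return adata


def qc_filter(adata: AnnData, thresholds: QCThresholds = QCThresholds()) -> tuple[AnnData, QCReport]:
    """Apply the cell gene-count and mito-fraction gates, then gene prevalence.

    All cell bounds are strict: a cell detecting exactly ``min_genes`` genes
    or with a mito fraction exactly at ``max_mito_fraction`` is removed.
    ``removed_by_rule`` counts each rule independently, so overlaps are
    visible (their sum can exceed the number of removed cells).
    """
    x = adata.X
    detected = (x > 0).sum(axis=1)
    detected = np.asarray(detected).ravel()
    total = np.asarray(x.sum(axis=1)).ravel()
    mito_mask = adata.var["mito"].to_numpy()
    mito_counts = np.asarray(x[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_counts / total, 1.0)

    low = detected <= thresholds.min_genes
    high = detected >= thresholds.max_genes
    mito_bad = mito_frac >= thresholds.max_mito_fraction
    keep_cells = ~(low | high | mito_bad)
    if not keep_cells.any():
        raise ValueError(
            "all cells removed by QC: "
            f"low_genes={int(low.sum())}, high_genes={int(high.sum())}, "
            f"high_mito={int(mito_bad.sum())}"
        )
    kept = adata[keep_cells].copy()
    gene_prevalence = np.asarray((kept.X > 0).sum(axis=0)).ravel()
    keep_genes = gene_prevalence >= thresholds.min_cells_per_gene
    out = kept[:, keep_genes].copy()
    report = QCReport(
        n_input_cells=adata.n_obs,
        n_retained_cells=out.n_obs,
        n_input_genes=adata.n_vars,
        n_retained_genes=out.n_vars,
        removed_by_rule={
            "low_genes": int(low.sum()),
            "high_genes": int(high.sum()),
            "high_mito": int(mito_bad.sum()),
            "gene_prevalence": int((~keep_genes).sum()),
        },
        removed_cells=list(adata.obs_names[~keep_cells]),
    )
    return out, report


def normalize_and_hvg(
    adata: AnnData,
    n_hvg: int = 3000,
    target_sum: float = 1e4,
) -> tuple[AnnData, list[str]]:
    """Depth-normalise to ``target_sum`` per cell, log1p, rank HVGs.

    HVGs are the top ``n_hvg`` genes by normalised dispersion (mean-binned,
    Seurat-style).  Raw counts are preserved in ``adata.layers['counts']``.
    Requesting more HVGs than genes returns all genes with a warning.
    """
    out = adata.copy()
    out.layers["counts"] = out.X.copy()
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    n = min(n_hvg, out.n_vars)
    if n < n_hvg:
        warnings.warn(
            f"requested {n_hvg} HVGs but only {out.n_vars} genes available"
        )
    sc.pp.highly_variable_genes(out, n_top_genes=n, flavor="seurat")
    hvg = list(out.var_names[out.var["highly_variable"]])
    return out, hvg


def cluster_cells(
    adata: AnnData,
    hvg: list[str],
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    n_pcs: int = 30,
) -> pd.Series:
    """PCA on scaled HVGs, SNN graph, Leiden communities (fixed seed).

    Returns a cell -> cluster-id Series (string ids).  Deterministic for a
    given seed.
    """
    if adata.n_obs < k_neighbors:
        raise ValueError("fewer cells than k_neighbors")
    sub = adata[:, [g for g in hvg if g in adata.var_names]].copy()
    sc.pp.scale(sub, max_value=10)
    n_comps = int(min(n_pcs, sub.n_obs - 1, sub.n_vars - 1))
    sc.tl.pca(sub, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(sub, n_neighbors=k_neighbors, random_state=seed)
    sc.tl.leiden(
        sub,
        resolution=resolution,
        random_state=seed,
        key_added="cluster",
        flavor="leidenalg",
        n_iterations=2,
    )
    return sub.obs["cluster"].astype(str).rename("cluster")


def downsample_per_cluster(
    clusters: pd.Series,
    n_per_cluster: int = 40,
    samples: pd.Series | None = None,
) -> list[str]:
    """First ``n_per_cluster`` barcodes per (sample, cluster), barcode-sorted.

    Barcode order is lexicographic, making the selection independent of the
    input ordering and idempotent; clusters smaller than ``n_per_cluster``
    are kept whole.  Returns the retained barcodes sorted lexicographically.
    """
    df = pd.DataFrame({"cluster": clusters.astype(str)})
    df["sample"] = samples.reindex(clusters.index).astype(str) if samples is not None else ""
    keep: list[str] = []
    for _, grp in df.groupby(["sample", "cluster"], sort=True):
        keep.extend(sorted(grp.index)[:n_per_cluster])
    return sorted(keep)


def annotate_cell_types(
    clusters: pd.Series,
    adata: AnnData,
    marker_table: dict[str, list[str]],
    min_margin: float = 0.1,
) -> pd.Series:
    """Label each cluster by its best-scoring marker set.

    The score of a cell type in a cluster is the mean z-scored expression of
    its marker genes over the cluster's cells.  The top type wins unless its
    margin over the runner-up falls below ``min_margin`` (ties included), in
    which case the cluster is labelled "unknown".  Markers absent from the
    matrix are skipped with a warning.
    """
    if not marker_table:
        return pd.Series(
            "unknown", index=clusters.astype(str).unique(), name="cell_type"
        )
    x = np.asarray(adata.X, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    zdf = pd.DataFrame(z, index=adata.obs_names, columns=adata.var_names)

    scores = {}
    for ctype, markers in marker_table.items():
        present = [g for g in markers if g in zdf.columns]
        missing = set(markers) - set(present)
        if missing:
            warnings.warn(f"markers absent for {ctype!r}: {sorted(missing)}")
        if not present:
            continue
        scores[ctype] = zdf[present].mean(axis=1)
    if not scores:
        return pd.Series(
            "unknown", index=clusters.astype(str).unique(), name="cell_type"
        )
    score_df = pd.DataFrame(scores)

    labels = {}
    for cl, grp in clusters.astype(str).groupby(clusters.astype(str)):
        m = score_df.loc[grp.index].mean(axis=0).sort_values(ascending=False)
        if len(m) > 1 and (m.iloc[0] - m.iloc[1]) < min_margin:
            labels[cl] = "unknown"
        else:
            labels[cl] = m.index[0]
    return pd.Series(labels, name="cell_type")


def module_celltype_correlation(
    eigengenes: pd.DataFrame,
    cell_types: pd.Series,
    gestational_week: pd.Series,
    *,
    type_r_min: float = 0.6,
    gw_r_max: float = 0.3,
    min_cells_per_level: int = 3,
) -> dict:
    """Correlate per-cell module eigengenes with one-hot traits.

    For every (module, cell-type level) and (module, gestational-week level)
    pair, the Pearson r between the eigengene and the 0/1 indicator is
    computed; levels with fewer than ``min_cells_per_level`` cells (or
    constant indicators) are reported as missing.  A module is flagged
    cell-type specific iff its max |r| over types exceeds ``type_r_min``,
    and developmentally stable iff all gestational-week |r| stay below
    ``gw_r_max``.

    Returns ``{"celltype_r": DataFrame, "gw_r": DataFrame,
    "celltype_specific": {module: best type or None}, "gw_stable": {module:
    bool}}``.
    """

    def onehot_corr(labels: pd.Series) -> pd.DataFrame:
        lab = labels.reindex(eigengenes.index)
        out = {}
        for level in sorted(lab.dropna().unique(), key=str):
            ind = (lab == level).astype(float)
            if ind.sum() < min_cells_per_level or ind.nunique() < 2:
                out[str(level)] = pd.Series(np.nan, index=eigengenes.columns)
                continue
            out[str(level)] = eigengenes.apply(
                lambda e: e.corr(ind) if e.std() > 0 else np.nan
            )
        return pd.DataFrame(out)

    ct_r = onehot_corr(cell_types)
    gw_r = onehot_corr(gestational_week)
    specific = {}
    for m in eigengenes.columns:
        row = ct_r.loc[m].abs()
        if row.notna().any() and row.max() > type_r_min:
            specific[m] = row.idxmax()
        else:
            specific[m] = None
    stable = {
        m: bool(gw_r.loc[m].abs().dropna().lt(gw_r_max).all())
        for m in eigengenes.columns
    }
    return {
        "celltype_r": ct_r,
        "gw_r": gw_r,
        "celltype_specific": specific,
        "gw_stable": stable,
    }
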
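"""Weighted co-expression network analysis (WGCNA-style), from scratch.

Pipeline: unsigned adjacency ``a_ij = |cor(x_i, x_j)|^beta`` (Pearson), the
topological overlap matrix (TOM) combining direct adjacency with shared
neighbourhoods, average-linkage hierarchical clustering of ``1 - TOM`` with
a conservative height-based tree cut (deepSplit=0 semantics), module
eigengenes (first principal component), module membership (kME) and gene
significance (GS), the GS-vs-MM module filter (cor > 0.4, p < 0.05), top-MM
hub selection, and export of the heaviest intra-module edges.

The tree cut is a height-cut approximation of the dynamic variant: deepSplit
maps to progressively lower cut heights on the dendrogram (0 = most
conservative, fewest splits).  Exact label equality with other
implementations is not a goal; planted-module recovery is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "MODULE_COLORS",
    "GREY",
    "SoftThreshold",
    "ModuleAssignment",
    "ModuleStats",
    "pick_soft_threshold",
    "adjacency",
    "adjacency_tom",
    "detect_modules",
    "module_eigengene",
    "gs_mm_filter",
    "select_hubs",
    "export_top_edges",
]

#: Deterministic module palette, assigned by decreasing module size.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]
GREY = "grey"  # unassigned features

# deepSplit -> cut height as a fraction of the top merge height
_CUT_FRACTION = {0: 0.99, 1: 0.97, 2: 0.95, 3: 0.93, 4: 0.91}


@dataclass
class SoftThreshold:
    power: int
    scale_free_fit: float  # signed R^2 of the log-log degree regression
    mean_connectivity: float
    reached_target: bool
    table: pd.DataFrame = field(repr=False, default=None)


@dataclass
class ModuleAssignment:
    labels: pd.Series  # feature -> color label ("grey" = unassigned)
    merge_heights: np.ndarray
    deepsplit: int
    min_module_size: int

    @property
    def modules(self) -> list[str]:
        """Non-grey module labels ordered by decreasing size."""
        counts = self.labels[self.labels != GREY].value_counts()
        return list(counts.index)

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


@dataclass
class ModuleStats:
    eigengenes: pd.DataFrame  # samples x modules
    mm: pd.DataFrame  # features x modules (kME)
    mm_p: pd.DataFrame
    gs: pd.Series  # feature -> cor(x, trait)
    gs_p: pd.Series
    gs_mm: pd.DataFrame  # per module: cor(|GS|, |MM|), p, n, passed


def _safe_corr(x: np.ndarray) -> np.ndarray:
    """Pearson feature-feature correlation; constant features -> 0, flagged."""
    constant = x.std(axis=1) == 0
    if constant.any():
        warnings.warn(f"{constant.sum()} constant feature(s); correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def adjacency(matrix: pd.DataFrame, power: int) -> np.ndarray:
    """Unsigned soft-threshold adjacency |cor|^beta with unit diagonal."""
    if power < 1:
        raise ValueError("power must be >= 1")
    a = np.abs(_safe_corr(matrix.to_numpy(dtype=float))) ** power
    np.fill_diagonal(a, 1.0)
    return a


def pick_soft_threshold(
    matrix: pd.DataFrame,
    candidate_powers: list[int] | None = None,
    *,
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> SoftThreshold:
    """Choose the soft-threshold power by the scale-free topology criterion.

    For each candidate power, the connectivity distribution is binned and
    log10(frequency) regressed on log10(mean connectivity); the signed fit
    ``-sign(slope) * R^2`` should be high for scale-free-like topology.
    Returns the smallest power reaching ``r2_target``, else the power with
    the maximum signed fit (flagged via ``reached_target=False``).
    """
    if matrix.shape[1] < 4:
        raise ValueError("need at least 4 samples for stable correlations")
    if candidate_powers is None:
        candidate_powers = list(range(1, 11)) + [12, 14, 16, 18, 20]
    rows = []
    for beta in candidate_powers:
        a = adjacency(matrix, beta)
        k = a.sum(axis=0) - 1.0  # exclude self
        k = k[k > 0]
        if len(k) < 2:
            rows.append({"power": beta, "r2": 0.0, "mean_k": float(np.mean(k)) if len(k) else 0.0})
            continue
        edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
        idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
        logk, logp = [], []
        for b in range(n_bins):
            sel = idx == b
            if sel.sum() == 0:
                continue
            logk.append(np.log10(k[sel].mean() + 1e-9))
            logp.append(np.log10(sel.mean() + 1e-9))
        if len(logk) < 3:
            r2 = 0.0
        else:
            fit = stats.linregress(logk, logp)
            r2 = -np.sign(fit.slope) * fit.rvalue**2
        rows.append({"power": beta, "r2": float(r2), "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    hit = table[table["r2"] >= r2_target]
    if len(hit):
        row = hit.iloc[0]
        reached = True
    else:
        row = table.loc[table["r2"].idxmax()]
        reached = False
        warnings.warn(
            f"no candidate power reached scale-free fit {r2_target}; "
            f"falling back to power {int(row['power'])} (R2={row['r2']:.3f})"
        )
    return SoftThreshold(
        power=int(row["power"]),
        scale_free_fit=float(row["r2"]),
        mean_connectivity=float(row["mean_k"]),
        reached_target=reached,
        table=table,
    )


def adjacency_tom(matrix: pd.DataFrame, power: int) -> pd.DataFrame:
    """Topological overlap similarity of the unsigned soft-threshold network.

    ``TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)``
    with ``k_i = sum_{u != i} a_iu``; the diagonal is 1.
    """
    a = adjacency(matrix, power)
    k = a.sum(axis=0) - 1.0
    shared = a @ a - 2.0 * a  # sum over u != i,j given unit diagonal
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=matrix.index, columns=matrix.index)


def detect_modules(
    tom: pd.DataFrame,
    deepsplit: int = 0,
    min_module_size: int = 30,
    matrix: pd.DataFrame | None = None,
    kme_min: float = 0.6,
) -> ModuleAssignment:
    """Cut the average-linkage dendrogram of ``1 - TOM`` into modules.

    Branches below the deepSplit-dependent cut height become candidate
    clusters; those smaller than ``min_module_size`` are left unassigned
    (grey).  Labels are color names ordered by module size (ties broken by
    first member position), so the labelling is deterministic.

    When the expression ``matrix`` is supplied, candidate modules are
    cleaned by eigengene membership: members with |kME| below ``kme_min``
    are released to grey (two refinement passes), which strips background
    features that attach to a branch by chance correlation in small-sample
    designs.  Modules falling below ``min_module_size`` after cleaning are
    dissolved.
    """
    if deepsplit not in _CUT_FRACTION:
        raise ValueError(f"deepsplit must be one of {sorted(_CUT_FRACTION)}")
    t = tom.to_numpy(dtype=float)
    if t.shape[0] != t.shape[1] or not np.allclose(t, t.T, atol=1e-8):
        raise ValueError("TOM must be square and symmetric")
    dissim = 1.0 - t
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    heights = z[:, 2]
    cut = _CUT_FRACTION[deepsplit] * heights.max() if len(heights) else 0.0
    raw = fcluster(z, t=cut, criterion="distance")

    ids, counts = np.unique(raw, return_counts=True)
    order = []
    for cid, cnt in zip(ids, counts):
        if cnt >= min_module_size:
            first = int(np.argmax(raw == cid))
            order.append((-int(cnt), first, cid))
    order.sort()
    if len(order) > len(MODULE_COLORS):
        raise ValueError("more modules than available color labels")
    mapping = {cid: MODULE_COLORS[i] for i, (_, _, cid) in enumerate(order)}
    labels = pd.Series(
        [mapping.get(c, GREY) for c in raw], index=tom.index, name="module"
    )
    if matrix is not None:
        labels = _kme_prune(matrix, labels, kme_min, min_module_size)
        labels = _relabel_by_size(labels)
    if (labels == GREY).all():
        warnings.warn("all features unassigned (grey)")
    return ModuleAssignment(
        labels=labels,
        merge_heights=heights,
        deepsplit=deepsplit,
        min_module_size=min_module_size,
    )


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    """Reassign palette names so color order tracks final module size."""
    order = []
    for m in [c for c in labels.unique() if c != GREY]:
        size = int((labels == m).sum())
        first = int(np.argmax((labels == m).to_numpy()))
        order.append((-size, first, m))
    order.sort()
    mapping = {m: MODULE_COLORS[i] for i, (_, _, m) in enumerate(order)}
    mapping[GREY] = GREY
    return labels.map(mapping)


def _kme_prune(
    matrix: pd.DataFrame,
    labels: pd.Series,
    kme_min: float,
    min_module_size: int,
    n_passes: int = 2,
) -> pd.Series:
    """Release weakly-connected members (|kME| < kme_min) to grey."""
    lab = labels.copy()
    for _ in range(n_passes):
        for m in [c for c in lab.unique() if c != GREY]:
            members = list(lab.index[lab == m])
            eg = module_eigengene(matrix, members)
            kme = matrix.loc[members].T.corrwith(eg).abs()
            lab.loc[kme.index[kme < kme_min]] = GREY
        for m in [c for c in lab.unique() if c != GREY]:
            if (lab == m).sum() < min_module_size:
                lab.loc[lab == m] = GREY
    return lab


def module_eigengene(matrix: pd.DataFrame, members: list[str]) -> pd.Series:
    """First principal component of the standardized module submatrix.

    Returned as a unit-norm sample-indexed vector, sign-fixed so that its
    correlation with the module's mean expression profile is positive.
    A single-feature module yields that feature standardized (unit norm).
    """
    sub = matrix.loc[members].to_numpy(dtype=float)
    sd = sub.std(axis=1)
    sd[sd == 0] = 1.0
    zs = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    if len(members) == 1:
        v = zs[0]
    else:
        _, _, vt = np.linalg.svd(zs, full_matrices=False)
        v = vt[0]
    norm = np.linalg.norm(v)
    if norm > 0:
        v = v / norm
    mean_profile = zs.mean(axis=0)
    if np.dot(v, mean_profile) < 0:
        v = -v
    return pd.Series(v, index=matrix.columns)


def _cor_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def gs_mm_filter(
    matrix: pd.DataFrame,
    assignment: ModuleAssignment,
    trait: pd.Series,
    *,
    cor_min: float = 0.4,
    alpha: float = 0.05,
) -> tuple[list[str], ModuleStats]:
    """Keep modules whose |GS| and |MM| correlate strongly over members.

    GS_i = cor(x_i, trait) (point-biserial for a 0/1 trait); MM_i,M =
    cor(x_i, eigengene_M).  Per module, cor(|GS|, |MM|) over its members is
    tested (Pearson correlation test); modules with cor > ``cor_min`` and
    p < ``alpha`` qualify.  Modules with fewer than 3 members cannot be
    tested and are excluded with a warning.
    """
    tr = trait.reindex(matrix.columns)
    if tr.isna().any():
        raise ValueError("trait must cover every sample")
    tvec = tr.to_numpy(dtype=float)
    x = matrix.to_numpy(dtype=float)

    modules = assignment.modules
    eg = pd.DataFrame(
        {m: module_eigengene(matrix, assignment.members(m)) for m in modules}
    )
    gs = pd.Series(index=matrix.index, dtype=float)
    gs_p = pd.Series(index=matrix.index, dtype=float)
    for i, f in enumerate(matrix.index):
        gs[f], gs_p[f] = _cor_with_p(x[i], tvec)
    mm = pd.DataFrame(index=matrix.index, columns=modules, dtype=float)
    mm_p = pd.DataFrame(index=matrix.index, columns=modules, dtype=float)
    for m in modules:
        e = eg[m].to_numpy()
        for i, f in enumerate(matrix.index):
            mm.loc[f, m], mm_p.loc[f, m] = _cor_with_p(x[i], e)

    rows, passed = [], []
    for m in modules:
        mem = assignment.members(m)
        if len(mem) < 3:
            warnings.warn(f"module {m!r} has fewer than 3 members; excluded")
            rows.append({"module": m, "cor": np.nan, "p": np.nan, "n": len(mem), "passed": False})
            continue
        r, p = _cor_with_p(
            gs.loc[mem].abs().to_numpy(), mm.loc[mem, m].abs().to_numpy()
        )
        ok = bool(r > cor_min and p < alpha)
        rows.append({"module": m, "cor": r, "p": p, "n": len(mem), "passed": ok})
        if ok:
            passed.append(m)
    stats_out = ModuleStats(
        eigengenes=eg,
        mm=mm,
        mm_p=mm_p,
        gs=gs,
        gs_p=gs_p,
        gs_mm=pd.DataFrame(rows).set_index("module"),
    )
    return passed, stats_out


def select_hubs(
    stats_: ModuleStats,
    assignment: ModuleAssignment,
    module: str,
    top_n: int = 5,
) -> list[str]:
    """Top-n features of a module by |kME|, ties broken lexicographically."""
    members = assignment.members(module)
    if not members:
        raise ValueError(f"module {module!r} has no members")
    if len(members) < top_n:
        warnings.warn(
            f"module {module!r} has {len(members)} members < top_n={top_n}; returning all"
        )
    mm = stats_.mm.loc[members, module].abs()
    ranked = sorted(members, key=lambda f: (-mm[f], f))
    return ranked[:top_n]


def export_top_edges(
    tom: pd.DataFrame,
    members: list[str],
    n_edges: int = 1000,
) -> pd.DataFrame:
    """Heaviest intra-module TOM edges, sorted by weight descending.

    Returns up to ``n_edges`` rows (all pairs if fewer exist) with columns
    source, target, weight; source < target lexicographically and ties in
    weight break by (source, target).
    """
    if not members:
        raise ValueError("module is empty")
    sub = tom.loc[members, members]
    rows = []
    ids = list(sub.index)
    vals = sub.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = sorted((ids[i], ids[j]))
            rows.append((a, b, float(vals[i, j])))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return pd.DataFrame(rows[:n_edges], columns=["source", "target", "weight"])
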
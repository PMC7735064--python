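"""Over-representation analysis (ORA) over user-supplied gene sets.

One-sided hypergeometric (Fisher) test of the overlap between a query gene
list and each set in a collection, against an explicit background universe,
with Benjamini-Hochberg adjustment across the collection.  Gene sets are
read from GMT files; which universe to use (array genes vs genome) is the
caller's choice and is a required input.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ora_test", "ora_collection", "read_gmt", "write_gmt"]


def ora_test(query: set[str], gene_set: set[str], universe: set[str]) -> dict:
    """Upper-tail hypergeometric probability of the observed overlap.

    p = P(X >= k) with X ~ Hypergeom(N=|universe|, K=|set ∩ universe|,
    n=|query|); fold enrichment = (k/n) / (K/N).
    """
    q = set(query) & set(universe)
    if not q:
        raise ValueError("query has no genes in the universe")
    s = set(gene_set) & set(universe)
    n_univ, n_set, n_query = len(universe), len(s), len(q)
    k = len(q & s)
    p = float(stats.hypergeom.sf(k - 1, n_univ, n_set, n_query))
    expected = n_set * n_query / n_univ
    fold = k / expected if expected > 0 else float("nan")
    return {"k": k, "n_set": n_set, "n_query": n_query,
            "n_universe": n_univ, "p": min(p, 1.0), "fold": fold}


def ora_collection(
    query: set[str],
    collection: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """ORA of a query against every set, BH-adjusted across the collection."""
    rows = []
    for set_id in sorted(collection):
        rows.append({"set": set_id, **ora_test(query, collection[set_id], universe)})
    df = pd.DataFrame(rows)
    if len(df):
        _, p_adj, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
        df["p_adj"] = p_adj
    return df.sort_values(["p", "set"]).reset_index(drop=True)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT format: one set per line, ``id<TAB>description<TAB>gene...``."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for set_id in sorted(sets):
        desc = (descriptions or {}).get(set_id, "")
        lines.append("\t".join([set_id, desc, *sorted(sets[set_id])]))
    Path(path).write_text("\n".join(lines) + "\n")
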
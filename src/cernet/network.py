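"""Assembly of the tripartite circRNA-miRNA-mRNA (ceRNA) networks.

Three constructions mirror the analysis stages: a bipartite circRNA-miRNA
sponge network; a multidimensional circRNA->miRNA->mRNA network built by the
top-k / shared-miRNA / top-k cascade; and the core ceRNA network restricted
to hub circRNAs, differentially expressed miRNAs and module-annotated DE
mRNAs, with iterative pruning of molecules that reach no DE mRNA.

The graph is layered: circRNA -> miRNA -> mRNA edges only, never a direct
circRNA-mRNA edge.  Sponge-direction consistency (circRNA and mRNA moving
together, opposite to the sequestered miRNA) is annotated on every complete
path but never used as a filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .targets import TargetEdge, score_and_rank, shared_target_filter

__all__ = [
    "CeRNANetwork",
    "build_circ_mirna_network",
    "build_multidim_network",
    "assemble_core_network",
    "annotate_direction_consistency",
    "module_flow_summary",
]

logger = logging.getLogger(__name__)

_KINDS = ("circRNA", "miRNA", "mRNA")


@dataclass
class CeRNANetwork:
    """Typed tripartite graph plus its derived (circ, miRNA, mRNA) paths."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_node(self, node_id: str, kind: str, *, de_direction: str = "ns",
                 module: str | None = None, cell_type: str | None = None,
                 hub: bool = False) -> None:
        if kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if hub and kind != "circRNA":
            raise ValueError("hub flag is reserved for circRNA nodes")
        existing = self.graph.nodes.get(node_id)
        if existing and existing["kind"] != kind:
            raise ValueError(f"node {node_id!r} already typed {existing['kind']!r}")
        self.graph.add_node(
            node_id, kind=kind, de_direction=de_direction, module=module,
            cell_type=cell_type, hub=hub,
        )

    def add_edge(self, source: str, target: str, score: float = 1.0) -> None:
        ks = self.graph.nodes[source]["kind"]
        kt = self.graph.nodes[target]["kind"]
        if (ks, kt) not in {("circRNA", "miRNA"), ("miRNA", "mRNA")}:
            raise ValueError(f"illegal edge layer {ks} -> {kt}")
        self.graph.add_edge(source, target, score=float(score), etype=f"{ks}-{kt}")

    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == kind
        )

    @property
    def triplets(self) -> list[tuple[str, str, str]]:
        """All complete circRNA -> miRNA -> mRNA paths, sorted."""
        out = []
        for m in self.nodes_of_kind("miRNA"):
            circs = sorted(
                u for u in self.graph.predecessors(m)
                if self.graph.nodes[u]["kind"] == "circRNA"
            )
            genes = sorted(
                v for v in self.graph.successors(m)
                if self.graph.nodes[v]["kind"] == "mRNA"
            )
            out.extend((c, m, g) for c in circs for g in genes)
        return sorted(out)

    def summary(self) -> dict:
        return {
            "n_circRNA": len(self.nodes_of_kind("circRNA")),
            "n_miRNA": len(self.nodes_of_kind("miRNA")),
            "n_mRNA": len(self.nodes_of_kind("mRNA")),
            "n_edges": self.graph.number_of_edges(),
            "n_triplets": len(self.triplets),
        }

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"id": n, **d} for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "type": d["etype"], "score": d["score"]}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows)

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        for _, d in g.nodes(data=True):  # GraphML cannot hold None
            for k, v in list(d.items()):
                if v is None:
                    d[k] = ""
        nx.write_graphml(g, path)


def _direction_of(table: pd.DataFrame | dict | None, node_id: str) -> str:
    if table is None:
        return "ns"
    if isinstance(table, dict):
        return table.get(node_id, "ns")
    if "direction" in table.columns:
        hit = table.loc[table.index == node_id, "direction"]
        return str(hit.iloc[0]) if len(hit) else "ns"
    return "ns"


def build_circ_mirna_network(
    circ_set: list[str],
    mirna_edges: list[TargetEdge],
    de_mirnas: pd.DataFrame | dict | None = None,
    circ_directions: pd.DataFrame | dict | None = None,
) -> CeRNANetwork:
    """Bipartite sponge network of DE circRNAs and their predicted miRNAs.

    ``mirna_edges`` carry (source=miRNA, target=circRNA) predictions; edges
    referencing circRNAs outside ``circ_set`` are rejected and logged.
    miRNA nodes get up/down/ns from the DE miRNA table.
    """
    net = CeRNANetwork()
    for c in circ_set:
        net.add_node(c, "circRNA", de_direction=_direction_of(circ_directions, c))
    for e in mirna_edges:
        if e.target not in set(circ_set):
            logger.warning("edge to unknown circRNA %r rejected", e.target)
            continue
        if e.source not in net.graph:
            net.add_node(e.source, "miRNA", de_direction=_direction_of(de_mirnas, e.source))
        net.add_edge(e.target, e.source, score=e.score)
    return net


def build_multidim_network(
    circ_mirna_edges: list[TargetEdge],
    mirna_mrna_edges: list[TargetEdge],
    top_k_mirna: int = 20,
    min_shared: int = 2,
    top_k_mrna: int = 5,
    de_mirnas: pd.DataFrame | dict | None = None,
    de_mrnas: pd.DataFrame | dict | None = None,
    circ_directions: pd.DataFrame | dict | None = None,
) -> CeRNANetwork:
    """circRNA -> miRNA -> mRNA cascade network.

    Per circRNA, keep the ``top_k_mirna`` sponged miRNAs; keep only miRNAs
    shared by at least ``min_shared`` circRNAs; per retained miRNA, keep its
    ``top_k_mrna`` mRNA targets.
    """
    circs = sorted({e.target for e in circ_mirna_edges})
    if len(circs) < min_shared:
        raise ValueError(
            f"need at least min_shared={min_shared} circRNAs, got {len(circs)}"
        )
    per_circ = score_and_rank(circ_mirna_edges, top_k_mirna, group_by="target")
    top_lists = {c: [e.source for e in es] for c, es in per_circ.items()}
    shared = shared_target_filter(top_lists, min_sources=min_shared)

    net = CeRNANetwork()
    for c in circs:
        net.add_node(c, "circRNA", de_direction=_direction_of(circ_directions, c))
    for c, es in per_circ.items():
        for e in es:
            if e.source not in shared:
                continue
            if e.source not in net.graph:
                net.add_node(e.source, "miRNA",
                             de_direction=_direction_of(de_mirnas, e.source))
            net.add_edge(c, e.source, score=e.score)
    if shared:
        mm = [e for e in mirna_mrna_edges if e.source in shared]
        if mm:
            per_mirna = score_and_rank(mm, top_k_mrna, group_by="source")
            for m, es in per_mirna.items():
                if m not in net.graph:
                    continue
                for e in es:
                    if e.target not in net.graph:
                        net.add_node(e.target, "mRNA",
                                     de_direction=_direction_of(de_mrnas, e.target))
                    net.add_edge(m, e.target, score=e.score)
    return net


def assemble_core_network(
    hub_circ: list[str],
    de_mirnas: pd.DataFrame | dict,
    de_mrnas: pd.DataFrame | dict,
    module_gene_map: dict[str, str],
    circ_mirna_edges: list[TargetEdge],
    mirna_mrna_edges: list[TargetEdge],
    circ_modules: dict[str, str] | None = None,
    module_cell_types: dict[str, str] | None = None,
    circ_directions: pd.DataFrame | dict | None = None,
) -> CeRNANetwork:
    """Core ceRNA network: hub circRNAs, DE miRNAs, module-annotated DE mRNAs.

    Edges are restricted to (hub circRNA -> DE miRNA) and (DE miRNA -> DE
    mRNA present in ``module_gene_map``); then miRNAs with no surviving mRNA
    target and circRNAs with no surviving miRNA are deleted iteratively
    until a fixed point.  Nodes carry module and cell-type annotations.
    The result is independent of the input edge order.
    """
    if not hub_circ:
        raise ValueError("empty hub circRNA set")
    de_mirna_set = set(de_mirnas.index) if isinstance(de_mirnas, pd.DataFrame) else set(de_mirnas)
    de_mrna_set = set(de_mrnas.index) if isinstance(de_mrnas, pd.DataFrame) else set(de_mrnas)
    hub_set = set(hub_circ)
    circ_modules = circ_modules or {}
    module_cell_types = module_cell_types or {}

    net = CeRNANetwork()
    for c in sorted(hub_set):
        mod = circ_modules.get(c)
        net.add_node(c, "circRNA", hub=True, module=mod,
                     de_direction=_direction_of(circ_directions, c))
    for e in sorted(circ_mirna_edges, key=lambda e: (e.target, e.source)):
        if e.target in hub_set and e.source in de_mirna_set:
            if e.source not in net.graph:
                net.add_node(e.source, "miRNA",
                             de_direction=_direction_of(de_mirnas, e.source))
            net.add_edge(e.target, e.source, score=e.score)
    for e in sorted(mirna_mrna_edges, key=lambda e: (e.source, e.target)):
        if (e.source in net.graph and e.target in de_mrna_set
                and e.target in module_gene_map):
            if e.target not in net.graph:
                mod = module_gene_map[e.target]
                net.add_node(e.target, "mRNA", module=mod,
                             cell_type=module_cell_types.get(mod),
                             de_direction=_direction_of(de_mrnas, e.target))
            net.add_edge(e.source, e.target, score=e.score)

    # prune molecules that reach no DE mRNA, cascading upward
    changed = True
    while changed:
        changed = False
        for m in net.nodes_of_kind("miRNA"):
            if net.graph.out_degree(m) == 0:
                net.graph.remove_node(m)
                changed = True
        for c in net.nodes_of_kind("circRNA"):
            if net.graph.out_degree(c) == 0:
                net.graph.remove_node(c)
                changed = True
    return net


def annotate_direction_consistency(network: CeRNANetwork) -> pd.DataFrame:
    """Flag every complete path by the sponge direction rule.

    A (circRNA, miRNA, mRNA) path is ``consistent`` iff the circRNA and
    mRNA share a direction that differs from the miRNA's; ``indeterminate``
    if any member is non-significant (ns); ``inconsistent`` otherwise.
    Annotation only — no path is removed.
    """
    rows = []
    for c, m, g in network.triplets:
        dc = network.graph.nodes[c]["de_direction"]
        dm = network.graph.nodes[m]["de_direction"]
        dg = network.graph.nodes[g]["de_direction"]
        if "ns" in (dc, dm, dg):
            flag = "indeterminate"
        elif dc == dg != dm:
            flag = "consistent"
        else:
            flag = "inconsistent"
        rows.append({"circRNA": c, "miRNA": m, "mRNA": g, "flag": flag})
    df = pd.DataFrame(rows, columns=["circRNA", "miRNA", "mRNA", "flag"])
    network.graph.graph["direction_consistency"] = df
    return df


def module_flow_summary(network: CeRNANetwork) -> dict[str, pd.DataFrame]:
    """Count mRNA nodes per (module, DE direction) and (module, cell type)."""
    rows = [
        {
            "gene": g,
            "module": network.graph.nodes[g]["module"] or "unassigned",
            "direction": network.graph.nodes[g]["de_direction"],
            "cell_type": network.graph.nodes[g]["cell_type"] or "unassigned",
        }
        for g in network.nodes_of_kind("mRNA")
    ]
    df = pd.DataFrame(rows, columns=["gene", "module", "direction", "cell_type"])
    by_dir = (
        df.groupby(["module", "direction"]).size().rename("n").reset_index()
        if len(df) else pd.DataFrame(columns=["module", "direction", "n"])
    )
    flow = (
        df.groupby(["module", "cell_type"]).size().rename("n").reset_index()
        if len(df) else pd.DataFrame(columns=["module", "cell_type", "n"])
    )
    return {"module_direction": by_dir, "module_celltype_flow": flow}
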
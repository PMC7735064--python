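"""ceRNA network assembly: layering, pruning, consistency, flows."""

import numpy as np
import pandas as pd
import pytest

from cernet import network as net_mod
from cernet import synthetic, targets
from cernet.network import (
    CeRNANetwork,
    annotate_direction_consistency,
    assemble_core_network,
    build_circ_mirna_network,
    build_multidim_network,
    module_flow_summary,
)
from cernet.targets import BindingSite, TargetEdge


def edge(mirna, transcript, n_8mer=1):
    sites = [BindingSite(transcript, i * 10, i * 10 + 8, "8mer", 8)
             for i in range(n_8mer)]
    return TargetEdge(mirna, transcript, sites)


class TestBipartite:
    def test_counts_match_construction_oracle(self):
        circs = [f"c{i}" for i in range(10)]
        edges = [edge(f"m{j}", c) for c in circs[:6] for j in range(3)]
        net = build_circ_mirna_network(circs, edges, de_mirnas={"m0": "up"})
        assert len(net.nodes_of_kind("circRNA")) == 10
        assert len(net.nodes_of_kind("miRNA")) == 3
        assert net.graph.number_of_edges() == 18
        assert net.graph.nodes["m0"]["de_direction"] == "up"
        assert net.graph.nodes["m1"]["de_direction"] == "ns"

    def test_empty_edge_list_gives_isolated_circrnas(self):
        net = build_circ_mirna_network([f"c{i}" for i in range(10)], [])
        assert len(net.nodes_of_kind("circRNA")) == 10
        assert net.graph.number_of_edges() == 0

    def test_unknown_circrna_edge_rejected_and_logged(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="cernet.network"):
            net = build_circ_mirna_network(["c1"], [edge("m1", "ghost")])
        assert "ghost" in caplog.text
        assert net.graph.number_of_edges() == 0


class TestMultidim:
    def _trio_edges(self):
        # 3 circRNAs; m_shared targeted by all, m_pair by two, m_solo by one
        cm = []
        for c in ("c1", "c2", "c3"):
            cm.append(edge("m_shared", c))
        cm.append(edge("m_pair", "c1"))
        cm.append(edge("m_pair", "c2"))
        cm.append(edge("m_solo", "c3"))
        mm = [edge(m, g) for m in ("m_shared", "m_pair", "m_solo")
              for g in (f"g_{m}_1", f"g_{m}_2")]
        return cm, mm

    def test_shared_filter_keeps_only_multi_circ_mirnas(self):
        cm, mm = self._trio_edges()
        net = build_multidim_network(cm, mm, top_k_mirna=20, min_shared=2, top_k_mrna=5)
        assert set(net.nodes_of_kind("miRNA")) == {"m_shared", "m_pair"}
        assert "m_solo" not in net.graph

    def test_mrna_layer_is_deduplicated_union(self):
        cm = [edge("m1", c) for c in ("c1", "c2", "c3")]
        mm = [edge("m1", g) for g in ("g1", "g2", "g3", "g4", "g5")]
        net = build_multidim_network(cm, mm, top_k_mirna=20, min_shared=2, top_k_mrna=5)
        assert len(net.nodes_of_kind("mRNA")) == 5
        assert net.summary()["n_triplets"] == 15

    def test_disjoint_targets_empty_downstream_layers(self):
        cm = [edge("m1", "c1"), edge("m2", "c2")]
        net = build_multidim_network(cm, [], top_k_mirna=20, min_shared=2)
        assert net.nodes_of_kind("miRNA") == []
        assert net.nodes_of_kind("mRNA") == []

    def test_too_few_circrnas_rejected(self):
        with pytest.raises(ValueError, match="min_shared"):
            build_multidim_network([edge("m1", "c1")], [], min_shared=2)


class TestCoreAssembly:
    def _inputs(self):
        cm = [edge("m1", "c1"), edge("m2", "c1"), edge("m2", "c2"), edge("m3", "c3")]
        mm = [edge("m1", "g1"), edge("m2", "g2"), edge("m3", "g_nonDE")]
        de_mirnas = {"m1": "down", "m2": "down", "m3": "down"}
        de_mrnas = {"g1": "up", "g2": "up"}
        module_map = {"g1": "brown", "g2": "green"}
        return cm, mm, de_mirnas, de_mrnas, module_map

    def test_pruning_cascade_removes_dead_branches(self):
        cm, mm, de_mi, de_mr, mod = self._inputs()
        net = assemble_core_network(["c1", "c2", "c3"], de_mi, de_mr, mod, cm, mm)
        # m3's only target is non-DE -> m3 deleted -> c3 has no miRNA -> deleted
        assert "m3" not in net.graph and "c3" not in net.graph
        assert set(net.nodes_of_kind("circRNA")) == {"c1", "c2"}

    def test_pruning_is_idempotent_fixed_point(self):
        cm, mm, de_mi, de_mr, mod = self._inputs()
        net = assemble_core_network(["c1", "c2", "c3"], de_mi, de_mr, mod, cm, mm)
        before = (sorted(net.graph.nodes), sorted(net.graph.edges))
        again = assemble_core_network(
            net.nodes_of_kind("circRNA"), de_mi, de_mr, mod, cm, mm
        )
        assert (sorted(again.graph.nodes), sorted(again.graph.edges)) == before

    def test_edge_order_independence(self):
        cm, mm, de_mi, de_mr, mod = self._inputs()
        a = assemble_core_network(["c1", "c2", "c3"], de_mi, de_mr, mod, cm, mm)
        b = assemble_core_network(["c1", "c2", "c3"], de_mi, de_mr, mod,
                                  cm[::-1], mm[::-1])
        assert sorted(a.graph.edges) == sorted(b.graph.edges)

    def test_empty_hub_set_rejected(self):
        with pytest.raises(ValueError, match="hub"):
            assemble_core_network([], {}, {}, {}, [], [])

    def test_planted_triplets_recovered_via_sequences(self, pools_default):
        tr = pools_default.truth
        cm = targets.scan_transcripts(pools_default.mirna_seqs,
                                      pools_default.circ_seqs, circular=True)
        mm = targets.scan_transcripts(pools_default.mirna_seqs,
                                      pools_default.utr_seqs)
        circs = sorted({t[0] for t in tr.triplets})
        d = tr.triplet_directions
        net = assemble_core_network(
            circs,
            {m: d[1] for _, m, _ in tr.triplets},
            {g: d[2] for _, _, g in tr.triplets},
            {g: "brown" for _, _, g in tr.triplets},
            cm, mm,
            circ_directions={c: d[0] for c in circs},
        )
        assert set(net.triplets) == set(tr.triplets)

    def test_pruning_never_removes_complete_path_nodes(self):
        cm, mm, de_mi, de_mr, mod = self._inputs()
        net = assemble_core_network(["c1", "c2", "c3"], de_mi, de_mr, mod, cm, mm)
        on_paths = {n for t in net.triplets for n in t}
        assert on_paths <= set(net.graph.nodes)
        assert set(net.graph.nodes) == on_paths  # nothing else survives


class TestTripartiteInvariant:
    def test_direct_circ_mrna_edge_rejected(self):
        net = CeRNANetwork()
        net.add_node("c1", "circRNA")
        net.add_node("g1", "mRNA")
        with pytest.raises(ValueError, match="illegal edge layer"):
            net.add_edge("c1", "g1")

    def test_hub_flag_restricted_to_circrnas(self):
        net = CeRNANetwork()
        with pytest.raises(ValueError, match="hub"):
            net.add_node("m1", "miRNA", hub=True)

    def test_kind_fixed_per_id(self):
        net = CeRNANetwork()
        net.add_node("x", "miRNA")
        with pytest.raises(ValueError, match="already typed"):
            net.add_node("x", "mRNA")


class TestDirectionConsistency:
    @pytest.mark.parametrize(
        "dirs,flag",
        [
            (("up", "down", "up"), "consistent"),
            (("up", "up", "up"), "inconsistent"),
            (("down", "up", "down"), "consistent"),
            (("up", "down", "down"), "inconsistent"),
            (("up", "ns", "up"), "indeterminate"),
        ],
    )
    def test_sponge_rule(self, dirs, flag):
        net = CeRNANetwork()
        net.add_node("c", "circRNA", de_direction=dirs[0])
        net.add_node("m", "miRNA", de_direction=dirs[1])
        net.add_node("g", "mRNA", de_direction=dirs[2])
        net.add_edge("c", "m")
        net.add_edge("m", "g")
        out = annotate_direction_consistency(net)
        assert out["flag"].tolist() == [flag]

    def test_planted_triplets_all_consistent(self, pools_default):
        tr = pools_default.truth
        cm = targets.scan_transcripts(pools_default.mirna_seqs,
                                      pools_default.circ_seqs, circular=True)
        mm = targets.scan_transcripts(pools_default.mirna_seqs,
                                      pools_default.utr_seqs)
        circs = sorted({t[0] for t in tr.triplets})
        d = tr.triplet_directions
        net = assemble_core_network(
            circs, {m: d[1] for _, m, _ in tr.triplets},
            {g: d[2] for _, _, g in tr.triplets},
            {g: "brown" for _, _, g in tr.triplets}, cm, mm,
            circ_directions={c: d[0] for c in circs},
        )
        out = annotate_direction_consistency(net)
        assert (out["flag"] == "consistent").all()


class TestFlowSummary:
    def _net(self, gene_rows):
        net = CeRNANetwork()
        net.add_node("c", "circRNA", de_direction="up")
        net.add_node("m", "miRNA", de_direction="down")
        net.add_edge("c", "m")
        for g, mod, ct, d in gene_rows:
            net.add_node(g, "mRNA", module=mod, cell_type=ct, de_direction=d)
            net.add_edge("m", g)
        return net

    def test_all_down_module_has_zero_up_count(self):
        net = self._net([("g1", "brown", "progenitor", "down"),
                         ("g2", "brown", "progenitor", "down"),
                         ("g3", "green", "ExN", "up")])
        out = module_flow_summary(net)["module_direction"]
        brown = out[out["module"] == "brown"]
        assert set(brown["direction"]) == {"down"}

    def test_flow_totals_conserve_mrna_count(self, rng):
        mods = ["brown", "green", "blue"]
        cts = ["ExN", "InN", "astrocyte"]
        rows = [
            (f"g{i}", rng.choice(mods), rng.choice(cts), rng.choice(["up", "down"]))
            for i in range(30)
        ]
        net = self._net(rows)
        out = module_flow_summary(net)
        assert out["module_celltype_flow"]["n"].sum() == 30
        assert out["module_direction"]["n"].sum() == 30

    def test_matches_groupby_oracle(self, rng):
        rows = [
            (f"g{i}", rng.choice(["m1", "m2"]), rng.choice(["A", "B"]),
             rng.choice(["up", "down"]))
            for i in range(25)
        ]
        net = self._net(rows)
        out = module_flow_summary(net)["module_celltype_flow"]
        df = pd.DataFrame(rows, columns=["gene", "module", "cell_type", "dir"])
        oracle = df.groupby(["module", "cell_type"]).size()
        for r in out.itertuples():
            assert oracle.loc[(r.module, r.cell_type)] == r.n


def test_graphml_export_round_trip(tmp_path, pools_default):
    import networkx as nx

    tr = pools_default.truth
    cm = targets.scan_transcripts(pools_default.mirna_seqs,
                                  pools_default.circ_seqs, circular=True)
    mm = targets.scan_transcripts(pools_default.mirna_seqs, pools_default.utr_seqs)
    circs = sorted({t[0] for t in tr.triplets})
    net = assemble_core_network(
        circs, {m: "down" for _, m, _ in tr.triplets},
        {g: "up" for _, _, g in tr.triplets},
        {g: "brown" for _, _, g in tr.triplets}, cm, mm,
    )
    p = tmp_path / "core.graphml"
    net.to_graphml(p)
    back = nx.read_graphml(p)
    assert set(back.nodes) == set(net.graph.nodes)
    assert back.number_of_edges() == net.graph.number_of_edges()
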
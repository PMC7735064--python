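"""Co-expression network: TOM oracle, module detection, GS/MM, hubs, edges."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cernet import synthetic
from cernet.coexpression import (
    GREY,
    adjacency_tom,
    detect_modules,
    export_top_edges,
    gs_mm_filter,
    module_eigengene,
    pick_soft_threshold,
    select_hubs,
)


def tom_oracle(a):
    """Direct double-loop evaluation of the topological overlap formula."""
    n = a.shape[0]
    k = a.sum(axis=0) - 1.0
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            t[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return t


def _df(x):
    return pd.DataFrame(
        x, index=[f"f{i}" for i in range(x.shape[0])],
        columns=[f"s{j}" for j in range(x.shape[1])],
    )


class TestTOM:
    def test_matches_brute_force_oracle(self, rng):
        mat = _df(rng.normal(size=(10, 8)))
        tom = adjacency_tom(mat, power=6).to_numpy()
        a = np.abs(np.corrcoef(mat.to_numpy())) ** 6
        np.fill_diagonal(a, 1.0)
        assert np.allclose(tom, tom_oracle(a), atol=1e-12)

    def test_two_features_reduce_to_adjacency(self, rng):
        mat = _df(rng.normal(size=(2, 10)))
        a12 = abs(np.corrcoef(mat.to_numpy())[0, 1]) ** 3
        tom = adjacency_tom(mat, power=3)
        assert tom.iloc[0, 1] == pytest.approx(a12, abs=1e-12)

    def test_perfectly_correlated_features_give_all_ones(self):
        base = np.linspace(0, 1, 10)
        mat = _df(np.vstack([base * c for c in (1.0, 2.0, 3.0, -1.5)]))
        tom = adjacency_tom(mat, power=6)
        assert np.allclose(tom.to_numpy(), 1.0, atol=1e-10)

    def test_symmetric_unit_diagonal_in_range(self, rng):
        mat = _df(rng.normal(size=(30, 12)))
        tom = adjacency_tom(mat, power=6).to_numpy()
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)
        assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_constant_feature_zeroed_with_warning(self, rng):
        x = rng.normal(size=(5, 10))
        x[2] = 3.14
        with pytest.warns(UserWarning, match="constant"):
            tom = adjacency_tom(_df(x), power=6)
        off = tom.iloc[2].drop("f2")
        assert (off < 0.2).all()  # no adjacency signal contributed


class TestSoftThreshold:
    def test_independent_features_trigger_fallback(self, rng):
        mat = _df(rng.normal(size=(60, 10)))
        with pytest.warns(UserWarning, match="falling back"):
            st = pick_soft_threshold(mat, candidate_powers=[1, 2], r2_target=0.999)
        assert not st.reached_target
        assert st.table is not None and len(st.table) == 2

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="4 samples"):
            pick_soft_threshold(_df(rng.normal(size=(10, 3))))

    def test_deterministic_for_fixed_input(self, bulk_default):
        a = pick_soft_threshold(bulk_default.matrix)
        b = pick_soft_threshold(bulk_default.matrix)
        assert a.power == b.power and a.scale_free_fit == b.scale_free_fit


class TestDetectModules:
    def test_planted_modules_recovered(self):
        cfg = synthetic.GeneratorConfig(seed=21, n_case=25, n_control=25)
        ds = synthetic.generate_bulk_circrna(cfg)
        tom = adjacency_tom(ds.matrix, 6)
        asg = detect_modules(tom, 0, 30, matrix=ds.matrix)
        truth = [ds.truth.module_map.get(f, -1) for f in ds.matrix.index]
        ari = adjusted_rand_score(truth, list(asg.labels))
        assert len(asg.modules) == 3
        assert ari >= 0.9

    def test_oversized_min_module_size_greys_everything(self, toy_matrix):
        tom = adjacency_tom(toy_matrix, 6)
        with pytest.warns(UserWarning, match="grey"):
            asg = detect_modules(tom, 0, min_module_size=100)
        assert (asg.labels == GREY).all()

    def test_duplicated_features_co_assigned(self):
        cfg = synthetic.GeneratorConfig(seed=5, n_case=20, n_control=20,
                                        n_modules=1, module_size=40, n_features=80)
        ds = synthetic.generate_bulk_circrna(cfg)
        mat = ds.matrix.copy()
        dup = mat.loc[["circ_00000"]].rename(index={"circ_00000": "twin"})
        mat = pd.concat([mat, dup])
        tom = adjacency_tom(mat, 6)
        asg = detect_modules(tom, 0, 30)
        assert asg.labels["twin"] == asg.labels["circ_00000"] != GREY

    def test_invalid_deepsplit_rejected(self, toy_matrix):
        tom = adjacency_tom(toy_matrix, 6)
        with pytest.raises(ValueError, match="deepsplit"):
            detect_modules(tom, deepsplit=9)

    def test_label_names_follow_size_rank(self):
        cfg = synthetic.GeneratorConfig(seed=2, n_case=25, n_control=25)
        ds = synthetic.generate_bulk_circrna(cfg)
        tom = adjacency_tom(ds.matrix, 6)
        asg = detect_modules(tom, 0, 30, matrix=ds.matrix)
        sizes = [len(asg.members(m)) for m in asg.modules]
        assert sizes == sorted(sizes, reverse=True)
        assert asg.modules[0] == "turquoise"


class TestEigengene:
    def test_identical_features_give_proportional_eigengene(self):
        base = np.sin(np.linspace(0, 3, 12))
        mat = _df(np.vstack([base, base, base]))
        eg = module_eigengene(mat, list(mat.index))
        z = (base - base.mean()) / base.std()
        cor = np.corrcoef(eg, z)[0, 1]
        assert abs(cor) == pytest.approx(1.0, abs=1e-10)
        assert cor > 0  # sign convention: positive vs mean profile

    def test_recovers_planted_factor(self, bulk_default):
        ds = bulk_default
        members = [f for f, m in ds.truth.module_map.items() if m == 0]
        eg = module_eigengene(ds.matrix, members)
        factor = ds.truth.module_factors["planted_0"]
        assert abs(np.corrcoef(eg, factor)[0, 1]) >= 0.9

    def test_negating_matrix_flips_eigengene(self, toy_matrix):
        members = list(toy_matrix.index[:6])
        eg = module_eigengene(toy_matrix, members)
        eg_neg = module_eigengene(-toy_matrix, members)
        assert np.allclose(eg.to_numpy(), -eg_neg.to_numpy(), atol=1e-10)

    def test_singleton_module_is_standardized_feature(self, toy_matrix):
        eg = module_eigengene(toy_matrix, ["f00"])
        row = toy_matrix.loc["f00"]
        z = (row - row.mean()) / row.std()
        z = z / np.linalg.norm(z)
        assert np.allclose(eg, z)

    def test_unit_norm(self, toy_matrix):
        eg = module_eigengene(toy_matrix, list(toy_matrix.index[:5]))
        assert np.linalg.norm(eg) == pytest.approx(1.0)


class TestGsMmFilter:
    @pytest.fixture(scope="class")
    def strong(self):
        cfg = synthetic.GeneratorConfig(
            seed=13, n_case=30, n_control=30, n_features=280, module_size=70,
            module_trait_cor=0.55, loading_spread=0.25,
        )
        ds = synthetic.generate_bulk_circrna(cfg)
        tom = adjacency_tom(ds.matrix, 6)
        asg = detect_modules(tom, 0, 30, matrix=ds.matrix)
        trait = (ds.groups == "case").astype(float)
        passed, stats = gs_mm_filter(ds.matrix, asg, trait)
        return ds, asg, passed, stats

    def test_trait_driving_modules_pass(self, strong):
        _, asg, passed, _ = strong
        assert len(asg.modules) == 3
        assert set(passed) == set(asg.modules)

    def test_null_trait_rarely_passes(self):
        # trait independent of all features: expected pass rate <= alpha
        hits = trials = 0
        for seed in range(6):
            cfg = synthetic.GeneratorConfig(
                seed=seed, n_case=20, n_control=20, module_trait_cor=0.0
            )
            ds = synthetic.generate_bulk_circrna(cfg)
            tom = adjacency_tom(ds.matrix, 6)
            asg = detect_modules(tom, 0, 30, matrix=ds.matrix)
            trait = (ds.groups == "case").astype(float)
            passed, _ = gs_mm_filter(ds.matrix, asg, trait)
            trials += len(asg.modules)
            hits += len(passed)
        assert trials >= 10
        assert hits / trials <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / trials)

    def test_tiny_module_excluded_with_warning(self, toy_matrix):
        from cernet.coexpression import ModuleAssignment

        labels = pd.Series(GREY, index=toy_matrix.index)
        labels.iloc[:2] = "turquoise"
        asg = ModuleAssignment(labels=labels, merge_heights=np.array([]),
                               deepsplit=0, min_module_size=2)
        trait = pd.Series([0.0, 1.0] * 6, index=toy_matrix.columns)
        with pytest.warns(UserWarning, match="fewer than 3"):
            passed, stats = gs_mm_filter(toy_matrix, asg, trait)
        assert passed == []
        assert not stats.gs_mm.loc["turquoise", "passed"]

    def test_mm_and_gs_bounded_by_one(self, strong):
        _, _, _, stats = strong
        assert stats.mm.abs().max().max() <= 1.0 + 1e-12
        assert stats.gs.abs().max() <= 1.0 + 1e-12


class TestHubsAndEdges:
    def test_three_modules_times_top5_gives_15_hubs(self, ):
        cfg = synthetic.GeneratorConfig(
            seed=13, n_case=30, n_control=30, n_features=280, module_size=70,
            module_trait_cor=0.55, loading_spread=0.25,
        )
        ds = synthetic.generate_bulk_circrna(cfg)
        tom = adjacency_tom(ds.matrix, 6)
        asg = detect_modules(tom, 0, 30, matrix=ds.matrix)
        trait = (ds.groups == "case").astype(float)
        passed, stats = gs_mm_filter(ds.matrix, asg, trait)
        hubs = [h for m in passed for h in select_hubs(stats, asg, m, top_n=5)]
        assert len(passed) == 3
        assert len(hubs) == 15 and len(set(hubs)) == 15

    def test_feature_equal_to_eigengene_ranks_first(self, bulk_default):
        ds = bulk_default
        members = [f for f, m in ds.truth.module_map.items() if m == 0]
        mat = ds.matrix.copy()
        eg = module_eigengene(mat, members)
        mat.loc[members[0]] = eg.to_numpy()  # perfect kME = 1
        from cernet.coexpression import ModuleAssignment

        labels = pd.Series(GREY, index=mat.index)
        labels[members] = "turquoise"
        asg = ModuleAssignment(labels, np.array([]), 0, 30)
        trait = (ds.groups == "case").astype(float)
        _, stats = gs_mm_filter(mat, asg, trait)
        hubs = select_hubs(stats, asg, "turquoise", top_n=5)
        assert hubs[0] == members[0]

    def test_small_module_returns_all_with_warning(self, toy_matrix):
        from cernet.coexpression import ModuleAssignment

        labels = pd.Series(GREY, index=toy_matrix.index)
        labels.iloc[:3] = "blue"
        asg = ModuleAssignment(labels, np.array([]), 0, 3)
        trait = pd.Series([0, 1] * 6, index=toy_matrix.columns, dtype=float)
        _, stats = gs_mm_filter(toy_matrix, asg, trait)
        with pytest.warns(UserWarning, match="returning all"):
            hubs = select_hubs(stats, asg, "blue", top_n=5)
        assert len(hubs) == 3

    def test_edge_export_combinatorial_bound(self, toy_matrix):
        tom = adjacency_tom(toy_matrix, 6)
        members = list(toy_matrix.index[:10])
        edges = export_top_edges(tom, members, n_edges=1000)
        assert len(edges) == 45

    def test_edge_export_matches_sort_oracle(self, rng, toy_matrix):
        tom = adjacency_tom(toy_matrix, 6)
        members = list(toy_matrix.index)
        got = export_top_edges(tom, members, n_edges=30)
        pairs = []
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                u, v = sorted((a, b))
                pairs.append((u, v, tom.loc[u, v]))
        oracle = sorted(pairs, key=lambda r: (-r[2], r[0], r[1]))[:30]
        assert [(r.source, r.target) for r in got.itertuples()] == [
            (u, v) for u, v, _ in oracle
        ]
        assert (got["weight"].diff().dropna() <= 1e-15).all()

    def test_n_edges_one_returns_heaviest_pair(self, toy_matrix):
        tom = adjacency_tom(toy_matrix, 6)
        got = export_top_edges(tom, list(toy_matrix.index), n_edges=1)
        assert len(got) == 1
        off = tom.where(~np.eye(len(tom), dtype=bool))
        assert got["weight"].iloc[0] == pytest.approx(off.max().max())


def test_module_labels_invariant_under_feature_permutation():
    cfg = synthetic.GeneratorConfig(seed=9, n_case=20, n_control=20)
    ds = synthetic.generate_bulk_circrna(cfg)
    tom = adjacency_tom(ds.matrix, 6)
    asg = detect_modules(tom, 0, 30, matrix=ds.matrix)
    perm = ds.matrix.sample(frac=1.0, random_state=0)
    tom_p = adjacency_tom(perm, 6)
    asg_p = detect_modules(tom_p, 0, 30, matrix=perm)
    # partitions agree up to label names
    lab = asg.labels.sort_index()
    lab_p = asg_p.labels.sort_index()
    assert adjusted_rand_score(lab, lab_p) == pytest.approx(1.0)
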
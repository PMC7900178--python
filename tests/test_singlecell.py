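"""Single-cell clustering, typing, specificity, networks and conservation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import mscnet
from mscnet.network import Module, ModuleHierarchy

from oracles import hypergeom_upper_tail


def _frame(arr, prefix="c"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


def _two_blobs(n_per=40, sep=50.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(30, n_per))
    b = rng.normal(sep, 1.0, size=(30, n_per))
    return _frame(np.abs(np.hstack([a, b])))


class TestClusterCells:
    def test_separated_blobs_two_pure_communities(self):
        values = _two_blobs()
        labels = mscnet.cluster_cells(values, k=8, seed=0)
        assert labels.nunique() == 2
        truth = [0] * 40 + [1] * 40
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_duplicate_cells_share_cluster(self):
        values = _two_blobs(n_per=20)
        dup = values.copy()
        dup.columns = [f"d{j}" for j in range(dup.shape[1])]
        both = pd.concat([values, dup], axis=1)
        labels = mscnet.cluster_cells(both, k=6, seed=0)
        for j in range(values.shape[1]):
            assert labels[f"c{j}"] == labels[f"d{j}"]

    def test_order_invariance(self):
        values = _two_blobs(seed=3)
        labels = mscnet.cluster_cells(values, k=8, seed=0)
        shuffled = values.sample(frac=1.0, axis=1, random_state=5)
        labels2 = mscnet.cluster_cells(shuffled, k=8, seed=0)
        assert adjusted_rand_score(
            labels.loc[values.columns], labels2.loc[values.columns]
        ) == 1.0

    def test_k_bounds(self):
        values = _two_blobs(n_per=5)
        with pytest.raises(ValueError):
            mscnet.cluster_cells(values, k=10)


class TestSelectK:
    def test_entropy_bounds_and_recovery(self, default_sc):
        _, values, truth = default_sc
        k, curve = mscnet.select_k_by_entropy(values, seed=0)
        assert (curve >= 0).all()
        assert 2 <= k <= int(np.sqrt(values.shape[1]))
        labels = mscnet.cluster_cells(values, k, seed=0)
        tru = [truth.cell_types[c] for c in labels.index]
        assert adjusted_rand_score(tru, labels) >= 0.8

    def test_flat_curve_warns_smallest_k(self):
        values = _frame(np.ones((20, 30)))  # indistinguishable cells
        with pytest.warns(UserWarning, match="flat"):
            k, _ = mscnet.select_k_by_entropy(values, k_range=(2, 4), seed=0)
        assert k == 2


class TestMarkers:
    def test_fold_boundary_strict(self):
        # gene0: cluster mean exactly 1.2x rest -> excluded; gene1: 1.5x -> marker
        n = 30
        jitter = np.tile([0.01, -0.01], n // 2)
        g0 = np.concatenate([6.0 + jitter[:n], 5.0 + jitter[:n]])
        g1 = np.concatenate([7.5 + jitter[:n], 5.0 + jitter[:n]])
        values = _frame(np.vstack([g0, g1]))
        clusters = pd.Series([0] * n + [1] * n, index=values.columns)
        out = mscnet.cluster_markers(values, clusters).set_index(["gene", "cluster"])
        assert out.loc[("g0", 0), "fold"] == pytest.approx(1.2)
        assert not out.loc[("g0", 0), "is_marker"]
        assert out.loc[("g1", 0), "is_marker"]

    def test_planted_markers_recovered_and_null_controlled(self, default_sc):
        _, values, truth = default_sc
        cells = pd.Series(truth.cell_types)
        clusters = cells.loc[values.columns].map(
            {t: i for i, t in enumerate(sorted(set(cells)))}
        )
        out = mscnet.cluster_markers(values, clusters)
        called = out[out["is_marker"]]
        for i, t in enumerate(sorted(truth.markers)):
            mk = set(truth.markers[t])
            got = set(called[called["cluster"] == i]["gene"])
            assert len(mk & got) / len(mk) >= 0.95
        # genes that are markers of no type are rarely called
        null_genes = set(values.index) - {
            g for gs in truth.markers.values() for g in gs
        }
        frac_null_called = len(set(called["gene"]) & null_genes) / len(null_genes)
        assert frac_null_called <= 0.05


class TestTyping:
    def test_refinement_corrects_isolated_mislabel(self, default_sc):
        _, values, truth = default_sc
        rng = np.random.default_rng(0)
        ref_cfg = mscnet.default_config(seed=31)
        rvals, rtruth = mscnet.generate_single_cell(ref_cfg)
        rlab = pd.Series(rtruth.cell_types).reindex(rvals.columns)
        model = mscnet.train_cell_type_model(rvals, rlab, rtruth.markers, seed=0)
        ann0 = mscnet.classify_cell_types(values, model, k_refine=0)
        ann = mscnet.classify_cell_types(values, model, k_refine=10)
        tru = pd.Series(truth.cell_types)
        acc0 = (ann0["cell_type"] == tru.loc[ann0.index]).mean()
        acc = (ann["cell_type"] == tru.loc[ann.index]).mean()
        assert acc >= acc0 - 0.01
        assert acc >= 0.9
        # k_refine=0 provenance is pure tree output
        assert (ann0["provenance"] == "tree").all()

    def test_no_training_cells_rejected(self, default_sc):
        _, values, truth = default_sc
        with pytest.raises(ValueError):
            mscnet.train_cell_type_model(
                values, pd.Series(dtype=object), truth.markers
            )


class TestSpecificity:
    def test_ubiquitous_gene_unassigned(self):
        rng = np.random.default_rng(1)
        values = _frame(np.abs(rng.normal(5, 1, size=(3, 60))) + 1.0)
        annot = pd.DataFrame(
            {"cell_type": ["A"] * 30 + ["B"] * 30}, index=values.columns
        )
        out = mscnet.gene_celltype_specificity(values, annot)
        assert np.allclose(out["p"], 1.0)
        assert not out["assigned"].any()

    def test_exclusive_gene_assigned_with_tiny_p(self):
        values = _frame(np.zeros((2, 200)))
        values.iloc[0, :50] = 3.0  # expressed exactly in type A's 50 cells
        values.iloc[1, :] = 1.0
        annot = pd.DataFrame(
            {"cell_type": ["A"] * 50 + ["B"] * 150}, index=values.columns
        )
        out = mscnet.gene_celltype_specificity(values, annot)
        row = out[(out["gene"] == "g0") & (out["cell_type"] == "A")].iloc[0]
        assert row["assigned"]
        assert row["p"] < 1e-10

    def test_scale_invariance_of_support(self):
        rng = np.random.default_rng(2)
        values = _frame(np.abs(rng.normal(2, 1, size=(5, 80))) * (rng.random((5, 80)) > 0.5))
        annot = pd.DataFrame(
            {"cell_type": ["A"] * 40 + ["B"] * 40}, index=values.columns
        )
        a = mscnet.gene_celltype_specificity(values, annot)
        b = mscnet.gene_celltype_specificity(values * 1000.0, annot)
        pd.testing.assert_frame_equal(a, b)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        values = _frame((rng.random((4, 25)) > 0.5).astype(float) * 2.0)
        annot = pd.DataFrame(
            {"cell_type": ["A"] * 10 + ["B"] * 15}, index=values.columns
        )
        out = mscnet.gene_celltype_specificity(values, annot)
        for _, row in out.iterrows():
            kt = 10 if row["cell_type"] == "A" else 15
            exact = hypergeom_upper_tail(
                25, int(row["expressing_cells"]), kt, int(row["overlap"])
            )
            assert row["p"] == pytest.approx(float(exact), abs=1e-12)


class TestScNetwork:
    def test_expression_count_boundary(self):
        rng = np.random.default_rng(4)
        n_cells = 60
        base = np.abs(rng.normal(3, 1, size=(10, n_cells))) + 0.5
        values = _frame(base)
        f = rng.standard_normal(n_cells)
        for i in range(6):  # correlated block so a network exists
            values.iloc[i] = np.abs(2 + f + 0.3 * rng.standard_normal(n_cells))
        expressed = np.abs(2 + f[:20]) + 0.5
        for row, n_expr in ((7, 20), (8, 19), (9, 20)):
            v = values.iloc[row].copy()
            v[:] = 0.0
            v.iloc[:n_expr] = expressed[:n_expr] + 0.001 * row
            values.iloc[row] = v
        # g7 and g9 co-vary over the same 20 expressing cells; g8 shows the
        # same pattern but in only 19 cells and must fall to the filter
        net, _ = mscnet.sc_network(values, min_cells=20, min_module_size=3)
        assert "g8" not in net.graph.nodes
        assert "g9" in net.graph.nodes and "g7" in net.graph.nodes

    def test_planted_program_recovered(self):
        rng = np.random.default_rng(5)
        n_cells = 120
        cfg = mscnet.default_config(
            seed=6, n_genes=100, n_cells=n_cells, module_spec=(), hazard_spec=(),
            cell_type_spec=(mscnet.CellTypeSpec("TypeA", n_cells),),
        )
        values, _ = mscnet.generate_single_cell(cfg)
        prog = list(values.index[40:65])
        f = rng.standard_normal(n_cells)
        z = np.sqrt(0.7) * f + np.sqrt(0.3) * rng.standard_normal((25, n_cells))
        values.loc[prog] = np.maximum(np.exp2(2.0 + z) - 1, 0)
        net, hier = mscnet.sc_network(values, min_cells=20, min_module_size=5, seed=0)
        net.check_invariants()
        best = max(
            len(set(m.genes) & set(prog)) / len(set(m.genes) | set(prog))
            for m in hier
            if m.parent_id is not None
        )
        assert best >= 0.6


def _mini_hier(name, genes_by_module, universe):
    hier = ModuleHierarchy()
    hier.modules[f"{name}_root"] = Module(f"{name}_root", None, frozenset(universe))
    hier.root_id = f"{name}_root"
    for mid, genes in genes_by_module.items():
        hier.modules[mid] = Module(mid, f"{name}_root", frozenset(genes))
    return hier


class TestConservation:
    def test_three_part_rule_boundaries(self):
        universe = [f"u{i}" for i in range(100)]
        bulk = _mini_hier("b", {"B1": universe[:10]}, universe)
        # FE exactly 2: k=2, m=n=10, N=100 -> not conserved despite overlap
        sc = _mini_hier("s", {"S1": universe[:2] + universe[50:58]}, universe)
        out = mscnet.module_conservation(bulk, sc, universe)
        row = out.iloc[0]
        assert row["fold_enrichment"] == pytest.approx(2.0)
        assert not row["conserved"]

    def test_identical_modules_conserved(self):
        universe = [f"u{i}" for i in range(1000)]
        bulk = _mini_hier("b", {"B1": universe[:50]}, universe)
        sc = _mini_hier("s", {"S1": universe[:50]}, universe)
        out = mscnet.module_conservation(bulk, sc, universe)
        row = out.iloc[0]
        assert row["fold_enrichment"] == pytest.approx(20.0)
        assert row["frac_bulk"] == 1.0 and row["frac_sc"] == 1.0
        assert row["conserved"]

    def test_overlap_fraction_rule(self):
        universe = [f"u{i}" for i in range(1000)]
        # 30% of bulk module but only 10% of the sc module -> not conserved
        bulk = _mini_hier("b", {"B1": universe[:10]}, universe)
        sc = _mini_hier("s", {"S1": universe[:3] + universe[100:127]}, universe)
        out = mscnet.module_conservation(bulk, sc, universe)
        row = out.iloc[0]
        assert row["frac_bulk"] == pytest.approx(0.3)
        assert row["frac_sc"] == pytest.approx(0.1)
        assert not row["conserved"]

    def test_symmetry_of_p_and_overlap(self):
        rng = np.random.default_rng(6)
        universe = [f"u{i}" for i in range(300)]
        b_genes = list(rng.choice(universe, 40, replace=False))
        s_genes = list(rng.choice(universe, 25, replace=False))
        bulk = _mini_hier("b", {"B1": b_genes}, universe)
        sc = _mini_hier("s", {"S1": s_genes}, universe)
        fwd = mscnet.module_conservation(bulk, sc, universe).iloc[0]
        rev = mscnet.module_conservation(sc, bulk, universe).iloc[0]
        assert fwd["p"] == pytest.approx(rev["p"], rel=1e-10)
        assert fwd["overlap"] == rev["overlap"]


class TestNeighborhoodValidation:
    @staticmethod
    def _path_net(n=100):
        import networkx as nx
        from test_network import edge_frame

        g = nx.path_graph(n)
        return mscnet.build_pfn(
            edge_frame([(f"n{u:03d}", f"n{v:03d}", 0.9) for u, v in g.edges])
        )

    def test_size_cap_returns_not_tested(self):
        net = self._path_net(100)
        sig = mscnet.GeneSignature("s", frozenset(["n000"]), "none")
        # 11-hop neighborhood of the chain end covers 12 nodes > 10% of 100
        res = mscnet.validate_neighborhood(net, "n000", sig, 11, net.vertices)
        assert not res["tested"]
        # 9 hops -> 10 nodes = 10%, tested
        res = mscnet.validate_neighborhood(net, "n000", sig, 9, net.vertices)
        assert res["tested"]

    def test_self_signature_validated(self):
        net = self._path_net(60)
        hood = mscnet.neighborhood(net, "n030", 2)
        sig = mscnet.GeneSignature("s", frozenset(hood), "none")
        res = mscnet.validate_neighborhood(net, "n030", sig, 2, net.vertices)
        assert bool(res["validated"])

    def test_negative_layer_rejected(self):
        net = self._path_net(20)
        sig = mscnet.GeneSignature("s", frozenset(["n000"]), "none")
        with pytest.raises(ValueError):
            mscnet.validate_neighborhood(net, "n000", sig, -1, net.vertices, 0.9)
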
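"""Enrichment, differential-connectivity and ranking tests."""

import numpy as np
import pandas as pd
import pytest

import mscnet
from mscnet.network import Module, ModuleHierarchy

from conftest import hierarchy_from_truth, small_cohort
from oracles import hypergeom_upper_tail


class TestFET:
    def test_worked_value(self):
        # N=20, m=n=5, k=4: p = [C(5,4)C(15,1)+C(5,5)C(15,0)]/C(20,5) = 76/15504
        universe = [f"u{i}" for i in range(20)]
        query = universe[:5]
        target = universe[1:5] + [universe[10]]
        res = mscnet.fet_enrichment(query, target, universe)
        assert res.overlap == 4
        assert res.p == pytest.approx(76 / 15504, abs=1e-12)
        assert res.fold_enrichment == pytest.approx(4 * 20 / 25)

    def test_saturation(self):
        u = list("abcdef")
        res = mscnet.fet_enrichment(u, u, u)
        assert res.p == pytest.approx(1.0) and res.fold_enrichment == pytest.approx(1.0)

    def test_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(5, 31))
            universe = [f"u{i}" for i in range(N)]
            m = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            query = list(rng.choice(universe, m, replace=False))
            target = list(rng.choice(universe, n, replace=False))
            res = mscnet.fet_enrichment(query, target, universe)
            exact = hypergeom_upper_tail(N, m, n, res.overlap)
            assert res.p == pytest.approx(float(exact), abs=1e-12)

    def test_fold_enrichment_hand_formula(self):
        universe = [f"u{i}" for i in range(100)]
        query, target = universe[:10], universe[5:15]
        res = mscnet.fet_enrichment(query, target, universe)
        assert res.overlap == 5
        assert res.fold_enrichment == pytest.approx(5 * 100 / (10 * 10))  # = 5

    def test_empty_sets_degenerate(self):
        res = mscnet.fet_enrichment([], ["a"], ["a", "b"])
        assert res.overlap == 0 and res.p == 1.0


class TestMDC:
    def test_self_ratio_is_one(self):
        cfg, expr, _, _, truth = small_cohort(seed=1)
        hier = hierarchy_from_truth(truth)
        norm = mscnet.normalize_expression(expr)
        out = mscnet.mdc_filter(hier, norm, norm, n_perm=100, seed=0)
        assert np.allclose(out["mdc"], 1.0)
        assert not out["mdc_retained"].any()

    def test_scale_invariance(self):
        cfg, expr, _, _, truth = small_cohort(seed=2)
        hier = hierarchy_from_truth(truth)
        norm = mscnet.normalize_expression(expr)
        ref = mscnet.normalize_expression(
            mscnet.generate_reference_cohort(cfg, truth, {"M1"})
        )
        a = mscnet.mdc_filter(hier, norm, ref, n_perm=100, seed=0)
        b = mscnet.mdc_filter(hier, norm.values * 7.0, ref, n_perm=100, seed=0)
        assert np.allclose(a["mdc"], b["mdc"])

    def test_rewired_module_flagged(self):
        cfg, expr, _, _, truth = small_cohort(seed=3, n_samples=150)
        hier = hierarchy_from_truth(truth)
        norm = mscnet.normalize_expression(expr)
        ref = mscnet.normalize_expression(
            mscnet.generate_reference_cohort(cfg, truth, {"M1"})
        )
        out = mscnet.mdc_filter(hier, norm, ref, n_perm=500, seed=0)
        assert bool(out.loc["M1", "mdc_retained"])
        assert out.loc["M1", "mdc"] > 1.0


class TestRanking:
    @staticmethod
    def _hier_with_parent_and_children():
        hier = ModuleHierarchy()
        universe = [f"u{i}" for i in range(500)]
        c1, c2 = frozenset(universe[:20]), frozenset(universe[20:40])
        hier.modules["P"] = Module("P", None, frozenset(universe))
        hier.modules["A"] = Module("A", "P", c1 | c2)
        hier.modules["A1"] = Module("A1", "A", c1)
        hier.modules["A2"] = Module("A2", "A", c2)
        hier.root_id = "P"
        return hier, universe

    def test_branch_dedup_trace(self):
        hier, universe = self._hier_with_parent_and_children()
        # signature concentrated in A1, one stray gene in A2: p(A1) < p(A) < p(A2)
        sig = mscnet.GeneSignature(
            "sig", frozenset(universe[:15]) | {universe[20]}, "up_poor"
        )
        out = mscnet.rank_modules(hier, None, sig, universe, min_size=5)
        ps = out["p"]
        assert ps["A1"] < ps["A"] < ps["A2"]
        assert set(out.index[out["retained"]]) == {"A1", "A2"}

    def test_flat_list_is_plain_p_sort(self):
        hier = ModuleHierarchy()
        universe = [f"u{i}" for i in range(300)]
        hier.modules["root"] = Module("root", None, frozenset(universe))
        hier.root_id = "root"
        rng = np.random.default_rng(3)
        for i in range(6):
            genes = frozenset(rng.choice(universe, 30, replace=False))
            hier.modules[f"F{i}"] = Module(f"F{i}", "root", genes)
        sig = mscnet.GeneSignature("sig", frozenset(universe[:40]), "up_poor")
        out = mscnet.rank_modules(hier, None, sig, universe, min_size=5)
        assert out["retained"].all()
        assert (out["p"].to_numpy() == np.sort(out["p"].to_numpy())).all()

    def test_retained_set_is_antichain_on_random_hierarchies(self):
        rng = np.random.default_rng(4)
        universe = [f"u{i}" for i in range(400)]
        for trial in range(100):
            hier = ModuleHierarchy()
            hier.modules["root"] = Module("root", None, frozenset(universe))
            hier.root_id = "root"
            frontier = [("root", list(universe))]
            count = 0
            while frontier and count < 12:
                pid, genes = frontier.pop(0)
                if len(genes) < 20:
                    continue
                n_children = int(rng.integers(2, 4))
                splits = np.array_split(rng.permutation(genes), n_children)
                for part in splits:
                    mid = f"m{count}"
                    count += 1
                    hier.modules[mid] = Module(mid, pid, frozenset(part))
                    if rng.random() < 0.5:
                        frontier.append((mid, list(part)))
            sig = mscnet.GeneSignature(
                "sig", frozenset(rng.choice(universe, 50, replace=False)), "up_poor"
            )
            out = mscnet.rank_modules(hier, None, sig, universe, min_size=3)
            retained = list(out.index[out["retained"]])
            for a in retained:
                for b in retained:
                    if a != b:
                        assert not hier.is_ancestor(a, b)


class TestAnnotateAndNominate:
    def test_identical_set_minimal_p(self):
        hier = ModuleHierarchy()
        universe = [f"u{i}" for i in range(200)]
        hier.modules["root"] = Module("root", None, frozenset(universe))
        hier.modules["A"] = Module("A", "root", frozenset(universe[:25]))
        hier.root_id = "root"
        colls = {
            "match": set(universe[:25]),
            "other": set(universe[100:150]),
            "disjoint_from_universe": {"zzz"},
        }
        out = mscnet.annotate_modules(hier, colls, universe)
        sub = out[out["module_id"] == "A"].set_index("gene_set")
        assert "disjoint_from_universe" not in sub.index
        assert sub["p"].idxmin() == "match"
        assert sub.loc["match", "overlap"] == 25

    def test_shuffled_labels_null_control(self):
        rng = np.random.default_rng(5)
        universe = [f"u{i}" for i in range(500)]
        hier = ModuleHierarchy()
        hier.modules["root"] = Module("root", None, frozenset(universe))
        hier.root_id = "root"
        for i in range(10):
            hier.modules[f"m{i}"] = Module(
                f"m{i}", "root", frozenset(rng.choice(universe, 40, replace=False))
            )
        colls = {
            f"gs{j}": set(rng.choice(universe, 40, replace=False)) for j in range(20)
        }
        out = mscnet.annotate_modules(hier, colls, universe)
        assert (out["cfet_p"] < 0.05).mean() <= 0.05

    def test_nomination_bookkeeping(self):
        ranking = pd.DataFrame(
            {
                "rank": [1, 2],
                "retained": [True, True],
                "p": [1e-8, 1e-4],
            },
            index=pd.Index(["A", "B"], name="module_id"),
        )
        hubs = pd.DataFrame(
            {
                "gene": ["h1", "h2", "h3", "x1"],
                "module_id": ["A", "B", "C", "A"],
                "degree": [30, 20, 25, 2],
                "p": [0.001, 0.002, 0.001, 0.9],
                "is_hub": [True, True, True, False],
            }
        )
        posg = mscnet.GeneSignature("POSG", frozenset(["h1", "h3", "x1"]), "up_poor")
        out = mscnet.nominate_regulators(ranking, hubs, posg, top_k=2)
        # h1: hub of top module and POSG -> in; h3's module not retained; x1 not hub
        assert list(out["gene"]) == ["h1"]
        assert out.iloc[0]["module_id"] == "A"
        with pytest.warns(UserWarning, match="exceeds"):
            mscnet.nominate_regulators(ranking, hubs, posg, top_k=10)

    def test_empty_intersection(self):
        ranking = pd.DataFrame(
            {"rank": [1], "retained": [True], "p": [1e-8]},
            index=pd.Index(["A"], name="module_id"),
        )
        hubs = pd.DataFrame(
            {"gene": ["h1"], "module_id": ["A"], "degree": [30], "p": [0.001],
             "is_hub": [True]}
        )
        posg = mscnet.GeneSignature("POSG", frozenset(["zzz"]), "up_poor")
        assert len(mscnet.nominate_regulators(ranking, hubs, posg, top_k=1)) == 0
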
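import numpy as np
import pandas as pd
import pytest

import mscnet
from mscnet.network import Module, ModuleHierarchy


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 4 planted 50-gene modules, r=0.7, n=200."""
    cfg = mscnet.default_config(seed=11)
    expr, surv, cov, truth = mscnet.generate_bulk_cohort(cfg)
    return cfg, expr, surv, cov, truth


@pytest.fixture(scope="session")
def default_norm(default_cohort):
    _, expr, _, cov, _ = default_cohort
    return mscnet.residualize(mscnet.normalize_expression(expr), cov)


@pytest.fixture(scope="session")
def default_network(default_norm):
    edges = mscnet.screen_correlations(default_norm)
    net = mscnet.build_pfn(edges)
    hier = mscnet.multiscale_cluster(net, min_module_size=10, seed=0)
    return edges, net, hier


@pytest.fixture(scope="session")
def default_sc():
    cfg = mscnet.default_config(seed=21)
    values, truth = mscnet.generate_single_cell(cfg)
    return cfg, values, truth


def hierarchy_from_truth(truth) -> ModuleHierarchy:
    """Planted modules as a flat hierarchy (root = all planted genes)."""
    hier = ModuleHierarchy()
    all_genes = frozenset(truth.module_chain)
    hier.modules["root"] = Module("root", None, all_genes)
    hier.root_id = "root"
    leaves = sorted({c[-1] for c in truth.module_chain.values()})
    for mid in leaves:
        genes = frozenset(
            g for g, c in truth.module_chain.items() if c[-1] == mid
        )
        hier.modules[mid] = Module(mid, "root", genes)
    return hier


def small_cohort(seed=0, n_genes=120, n_samples=100, module_sizes=(25, 25), r=0.7,
                 hazard=()):
    spec = tuple(
        mscnet.ModuleSpec(f"M{i+1}", None, s, r) for i, s in enumerate(module_sizes)
    )
    cfg = mscnet.SimulationConfig(
        n_genes=n_genes, n_samples=n_samples, module_spec=spec,
        hazard_spec=hazard, seed=seed,
    )
    return cfg, *mscnet.generate_bulk_cohort(cfg)
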
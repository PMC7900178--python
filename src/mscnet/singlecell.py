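"""Single-cell clustering, typing, specificity, networks and conservation.

Cells are clustered on a symmetrized k-nearest-neighbor graph built in the
first principal components of log-scale expression, with walktrap community
detection; the neighborhood size k is chosen by the elbow of the cluster-size
entropy curve over k in [2, floor(sqrt(N_c))].  Cell types are assigned by a
decision tree trained on marker features of labeled reference cells, then
refined by the type most enriched among each cell's nearest neighbors.
Per-cluster co-expression networks reuse the planar-filtered-network stack
(Spearman screen after a >= 20 expressing-cell gene filter), and bulk vs
single-cell module conservation is called by a three-part rule: Bonferroni
FET p < 0.05, fold enrichment > 2, and >= 30% overlap of both modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata, ttest_ind
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

from .network import (
    ModuleHierarchy,
    PlanarNetwork,
    bh_adjust,
    build_pfn,
    multiscale_cluster,
    neighborhood,
    screen_correlations,
)
from .prioritize import fet_enrichment
from .containers import GeneSignature

__all__ = [
    "log_transform",
    "pc_embedding",
    "cluster_cells",
    "select_k_by_entropy",
    "cluster_markers",
    "CellTypeModel",
    "train_cell_type_model",
    "classify_cell_types",
    "gene_celltype_specificity",
    "sc_network",
    "module_conservation",
    "validate_neighborhoods",
    "validate_neighborhood",
]


def log_transform(values: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM + 1); the pipeline's working scale for distances and tests."""
    return np.log2(values + 1.0)


def pc_embedding(values: pd.DataFrame, n_pcs: int = 10, seed: int = 0) -> np.ndarray:
    """Cells x n_pcs embedding of log-scale expression (deterministic SVD)."""
    x = log_transform(values).to_numpy(dtype=float).T  # cells x genes
    n_pcs = min(n_pcs, min(x.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    return pca.fit_transform(x)


def _knn_graph(embedding: np.ndarray, k: int) -> ig.Graph:
    """Union-symmetrized kNN graph on Euclidean distances in PC space."""
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:  # skip self
            edges.add((min(i, int(j)), max(i, int(j))))
    return ig.Graph(n=n, edges=sorted(edges))


def cluster_cells(
    values: pd.DataFrame,
    k: int,
    n_pcs: int = 10,
    seed: int = 0,
    walktrap_steps: int = 4,
) -> pd.Series:
    """Walktrap communities of the kNN graph in PC space.

    Returns a cell-indexed Series of integer cluster labels.  Cells are
    embedded in sorted-id order internally, so the result is invariant to the
    input column order at a fixed seed.
    """
    if k >= values.shape[1]:
        raise ValueError("k must be smaller than the number of cells")
    if k < 1:
        raise ValueError("k must be positive")
    order = np.argsort(values.columns)
    ordered = values.iloc[:, order]
    emb = pc_embedding(ordered, n_pcs=n_pcs, seed=seed)
    g = _knn_graph(emb, k)
    dendro = g.community_walktrap(steps=walktrap_steps)
    labels = np.asarray(dendro.as_clustering().membership)
    out = pd.Series(labels, index=ordered.columns, name="cluster")
    return out.reindex(values.columns)


def select_k_by_entropy(
    values: pd.DataFrame, n_pcs: int = 10, k_range=None, seed: int = 0
):
    """Choose the kNN size by the elbow of the cluster-size entropy curve.

    For each k the cells are clustered and the Shannon entropy of the
    cluster-size proportions is computed; the elbow is the k with maximum
    perpendicular distance to the chord joining the curve's endpoints.
    Returns ``(k, curve)`` with the curve as a k-indexed Series.
    """
    n_cells = values.shape[1]
    if k_range is None:
        k_range = (2, int(np.floor(np.sqrt(n_cells))))
    lo, hi = k_range
    if n_cells < 9 or hi < lo:
        raise ValueError("need at least 9 cells for a non-degenerate k range")

    ks = list(range(lo, hi + 1))
    ent = []
    for k in ks:
        labels = cluster_cells(values, k, n_pcs=n_pcs, seed=seed)
        props = labels.value_counts(normalize=True).to_numpy()
        ent.append(float(-(props * np.log(props)).sum()))
    curve = pd.Series(ent, index=pd.Index(ks, name="k"), name="entropy")

    if np.allclose(curve.to_numpy(), curve.iloc[0]):
        warnings.warn("flat entropy curve; returning the smallest k")
        return ks[0], curve

    # max perpendicular distance to the chord between the curve endpoints
    x = np.asarray(ks, dtype=float)
    y = curve.to_numpy()
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    num = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0)
    dist = num / np.hypot(y1 - y0, x1 - x0)
    return int(x[int(np.argmax(dist))]), curve


def cluster_markers(
    values: pd.DataFrame,
    clusters: pd.Series,
    fdr: float = 0.05,
    min_fold: float = 1.2,
) -> pd.DataFrame:
    """Cluster-vs-rest markers: Welch t on log scale, BH per cluster, linear fold.

    A gene is a marker of a cluster iff BH FDR < ``fdr`` and the ratio of
    linear-scale means (cluster over rest) strictly exceeds ``min_fold``.
    All-zero genes are skipped.
    """
    clusters = clusters.reindex(values.columns)
    logged = log_transform(values)
    lin = values.to_numpy(dtype=float)
    lx = logged.to_numpy(dtype=float)
    nonzero = lin.sum(axis=1) > 0
    genes = values.index[nonzero]
    lin, lx = lin[nonzero], lx[nonzero]

    out = []
    for cl in sorted(clusters.unique()):
        mask = (clusters == cl).to_numpy()
        if mask.sum() < 3 or (~mask).sum() < 3:
            raise ValueError(f"cluster {cl} (or its complement) has < 3 cells")
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = ttest_ind(lx[:, mask], lx[:, ~mask], axis=1, equal_var=False)
        p = np.where(np.isfinite(p), p, 1.0)
        q = bh_adjust(p)
        mean_in = lin[:, mask].mean(axis=1)
        mean_out = lin[:, ~mask].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.where(mean_out > 0, mean_in / mean_out, np.inf)
        is_marker = (q < fdr) & (fold > min_fold)
        out.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "cluster": cl,
                    "p": p,
                    "fdr": q,
                    "fold": fold,
                    "is_marker": is_marker,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# cell typing

@dataclass
class CellTypeModel:
    """Decision tree over marker features plus the marker reference table."""

    tree: DecisionTreeClassifier
    marker_features: list[str]
    types: list[str]


def train_cell_type_model(
    reference_values: pd.DataFrame,
    reference_labels: pd.Series,
    marker_table: dict[str, list[str]],
    seed: int = 0,
) -> CellTypeModel:
    """Fit the typing tree on labeled reference cells.

    Features are the log-scale expressions of the union of marker genes; the
    tree depth is capped at (number of reference types + 2).
    """
    if len(reference_labels) == 0:
        raise ValueError("no labeled training cells")
    features = sorted({g for gs in marker_table.values() for g in gs})
    present = [g for g in features if g in reference_values.index]
    types = sorted(set(reference_labels))
    for t in types:
        if not any(g in reference_values.index for g in marker_table.get(t, [])):
            raise ValueError(f"reference type {t!r} has no marker in the matrix")
    x = log_transform(reference_values.loc[present]).to_numpy(dtype=float).T
    y = reference_labels.reindex(reference_values.columns).to_numpy()
    tree = DecisionTreeClassifier(max_depth=len(types) + 2, random_state=seed)
    tree.fit(x, y)
    return CellTypeModel(tree=tree, marker_features=present, types=types)


def classify_cell_types(
    values: pd.DataFrame,
    model: CellTypeModel,
    k_refine: int = 10,
    n_pcs: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Decision-tree typing refined by kNN neighborhood majority.

    After the tree prediction each cell is reassigned to the type most
    over-represented among its ``k_refine`` nearest neighbors in PC space
    (ties broken by hypergeometric enrichment, then type name).  With
    ``k_refine=0`` the tree output is returned unchanged.  Provenance records
    whether the label came from the tree or the refinement.
    """
    feats = [g for g in model.marker_features if g in values.index]
    x = log_transform(values.loc[feats]).to_numpy(dtype=float).T
    tree_labels = model.tree.predict(x)
    out = pd.DataFrame(
        {"cell": values.columns, "cell_type": tree_labels, "provenance": "tree"}
    ).set_index("cell")

    if k_refine <= 0:
        return out

    emb = pc_embedding(values, n_pcs=n_pcs, seed=seed)
    n = emb.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k_refine + 1, n)).fit(emb)
    _, idx = nn.kneighbors(emb)
    labels = np.asarray(tree_labels)
    totals = pd.Series(labels).value_counts()

    refined = labels.copy()
    for i in range(n):
        neigh = labels[idx[i, 1:]]
        counts = pd.Series(neigh).value_counts()
        best = counts.max()
        tied = sorted(counts[counts == best].index)
        if len(tied) > 1:
            # hypergeometric enrichment of each tied type among the neighbors
            scores = {
                t: hypergeom.sf(counts[t] - 1, n, int(totals.get(t, 0)), len(neigh))
                for t in tied
            }
            winner = min(tied, key=lambda t: (scores[t], t))
        else:
            winner = tied[0]
        refined[i] = winner
    changed = refined != labels
    out["cell_type"] = refined
    out.loc[changed, "provenance"] = "knn_refined"
    return out


def gene_celltype_specificity(
    values: pd.DataFrame, annotation: pd.DataFrame, fdr: float = 0.05
) -> pd.DataFrame:
    """Assign genes to cell types by enrichment of their expressing cells.

    For each gene the expressing-cell set is {cells with value > 0 on the
    linear scale}; each (gene, type) pair is tested by FET against the type's
    cells over all cells, BH-corrected globally.  Genes expressed in zero
    cells are skipped.
    """
    cells = values.columns
    types = annotation.loc[cells, "cell_type"]
    x = values.to_numpy(dtype=float) > 0
    n = len(cells)
    rows = []
    for t in sorted(types.unique()):
        in_type = (types == t).to_numpy()
        kt = int(in_type.sum())
        k_expr = x.sum(axis=1)
        k_both = x[:, in_type].sum(axis=1)
        for gi, gene in enumerate(values.index):
            if k_expr[gi] == 0:
                continue
            p = float(hypergeom.sf(k_both[gi] - 1, n, kt, int(k_expr[gi])))
            rows.append((gene, t, int(k_both[gi]), int(k_expr[gi]), p))
    out = pd.DataFrame(
        rows, columns=["gene", "cell_type", "overlap", "expressing_cells", "p"]
    )
    if len(out):
        out["fdr"] = bh_adjust(out["p"])
        out["assigned"] = out["fdr"] < fdr
    return out


# ---------------------------------------------------------------------------
# per-cluster networks and conservation

def sc_network(
    values: pd.DataFrame,
    cells=None,
    min_cells: int = 20,
    fdr: float = 0.05,
    min_module_size: int = 10,
    alpha_grid=(0.5, 1.0, 1.5, 2.0),
    seed: int = 0,
) -> tuple[PlanarNetwork, ModuleHierarchy]:
    """Planar filtered network + module hierarchy for one cell cluster.

    Genes expressed (value > 0) in fewer than ``min_cells`` cells are dropped;
    the surviving genes are screened by Spearman correlation at FDR <
    ``fdr`` and passed through the PFN / multiscale clustering stack.
    """
    sub = values if cells is None else values[list(cells)]
    if sub.shape[1] < min_cells:
        raise ValueError("cluster has fewer cells than min_cells")
    expressed = (sub.to_numpy(dtype=float) > 0).sum(axis=1) >= min_cells
    filtered = sub.loc[sub.index[expressed]]
    if filtered.shape[0] < 2:
        raise ValueError("fewer than 2 genes survive the expression filter")
    edges = screen_correlations(log_transform(filtered), method="spearman", fdr_threshold=fdr)
    if len(edges) == 0:
        raise ValueError("no significant correlations; empty network")
    net = build_pfn(edges)
    hier = multiscale_cluster(net, alpha_grid=alpha_grid, min_module_size=min_module_size, seed=seed)
    return net, hier


def module_conservation(
    bulk: ModuleHierarchy, sc: ModuleHierarchy, universe
) -> pd.DataFrame:
    """Bulk vs single-cell module overlap with the three-part conservation rule.

    Every (bulk module, sc module) pair is tested by FET; Bonferroni is over
    all tested pairs.  A pair is conserved iff Bonferroni p < 0.05, fold
    enrichment > 2 (strict), and the overlap covers at least 30% of the genes
    of *each* module.
    """
    universe = set(universe)
    bmods = [m for m in bulk if m.parent_id is not None]
    smods = [m for m in sc if m.parent_id is not None]
    rows = []
    for bm in bmods:
        for sm in smods:
            res = fet_enrichment(bm.genes, sm.genes, universe)
            f_b = res.overlap / len(bm.genes & universe) if bm.genes & universe else 0.0
            f_s = res.overlap / len(sm.genes & universe) if sm.genes & universe else 0.0
            rows.append(
                (
                    bm.module_id,
                    sm.module_id,
                    res.overlap,
                    res.p,
                    res.fold_enrichment,
                    f_b,
                    f_s,
                )
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "bulk_module",
            "sc_module",
            "overlap",
            "p",
            "fold_enrichment",
            "frac_bulk",
            "frac_sc",
        ],
    )
    if not len(out):
        out["bonferroni_p"] = pd.Series(dtype=float)
        out["conserved"] = pd.Series(dtype=bool)
        return out
    out["bonferroni_p"] = np.minimum(out["p"] * len(out), 1.0)
    out["conserved"] = (
        (out["bonferroni_p"] < 0.05)
        & (out["fold_enrichment"] > 2.0)
        & (out["frac_bulk"] >= 0.30)
        & (out["frac_sc"] >= 0.30)
    )
    out.attrs["bonferroni_family"] = "all tested module pairs"
    return out


# ---------------------------------------------------------------------------
# perturbation-signature neighborhoods

def validate_neighborhoods(
    net: PlanarNetwork,
    tests: list[tuple[str, int]],
    signature: GeneSignature,
    universe,
    max_fraction: float = 0.10,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """FET of a perturbation signature in l-layer network neighborhoods.

    Each (gene, l) test takes the gene's l-hop neighborhood; neighborhoods
    covering more than ``max_fraction`` of the network are returned as
    not-tested.  BH correction runs across the tested set; ``validated`` is
    corrected p < ``fdr``.
    """
    universe = set(universe)
    n_nodes = net.graph.number_of_nodes()
    rows = []
    for gene, l in tests:
        if l < 0:
            raise ValueError("l must be non-negative")
        hood = neighborhood(net, gene, l)
        if len(hood) > max_fraction * n_nodes:
            rows.append((gene, l, len(hood), False, np.nan, np.nan, np.nan))
            continue
        res = fet_enrichment(hood, signature.genes, universe)
        rows.append((gene, l, len(hood), True, res.overlap, res.p, res.fold_enrichment))
    out = pd.DataFrame(
        rows,
        columns=["gene", "l", "neighborhood_size", "tested", "overlap", "p", "fold_enrichment"],
    )
    out["fdr"] = np.nan
    tested = out["tested"].to_numpy()
    if tested.any():
        out.loc[tested, "fdr"] = bh_adjust(out.loc[tested, "p"])
    out["validated"] = out["fdr"] < fdr
    return out


def validate_neighborhood(
    net: PlanarNetwork,
    gene: str,
    signature: GeneSignature,
    l: int,
    universe,
    max_fraction: float = 0.10,
):
    """Single-test convenience wrapper around :func:`validate_neighborhoods`."""
    return validate_neighborhoods(net, [(gene, l)], signature, universe, max_fraction).iloc[0]
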
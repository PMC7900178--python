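"""Planar filtered co-expression networks and their multiscale module hierarchy.

The construction follows the embedded network recipe: all pairwise
correlations are screened at FDR < 0.05, the surviving pairs are sorted by
|correlation| and embedded greedily, keeping an edge only if the accumulated
graph stays planar, until the planar edge cap 3(|V| - 2) is hit or the list is
exhausted.  The resulting planar filtered network (PFN) is decomposed top-down
by multiscale clustering: each parent module is partitioned by modularity
optimization and the split is accepted at the smallest resolution ``alpha`` at
which every child is more compact than the parent, where compactness is

    upsilon = mean_shortest_path_distance / (log |V|) ** alpha

(natural log by default; unweighted hop distances).  Hubs are module genes
whose within-module degree exceeds the degree of label-permuted networks at
p < 0.05.

Two exact shortcuts keep the greedy embedding fast without changing its
result: an edge joining two distinct planar components is always planar (no
test needed), and an edge inside a component that already holds 3n - 6 edges
can never be added (a maximal planar graph admits no further edge).
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import shortest_path
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = [
    "screen_correlations",
    "build_pfn",
    "PlanarNetwork",
    "compactness",
    "CompactnessParams",
    "multiscale_cluster",
    "Module",
    "ModuleHierarchy",
    "detect_hubs",
    "neighborhood",
    "bh_adjust",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# correlation screening

def _corr_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a correlation coefficient via the t distribution."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def screen_correlations(
    expr,
    method: str = "pearson",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """All-pairs correlation screen with BH control, sorted by |r| descending.

    Parameters
    ----------
    expr
        :class:`ExpressionMatrix` or genes x samples DataFrame.
    method
        ``pearson`` or ``spearman``.

    Returns
    -------
    DataFrame with columns ``gene_a, gene_b, correlation, p, adjusted_p``,
    only pairs with ``adjusted_p < fdr_threshold``, sorted by |correlation|
    descending with lexicographic (gene_a, gene_b) tie-break.  Constant genes
    are excluded with a warning.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    x = values.to_numpy(dtype=float)
    genes = np.asarray(values.index)

    keep = x.std(axis=1) > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} constant gene(s) from the screen"
        )
        x, genes = x[keep], genes[keep]
    if x.shape[0] < 2:
        raise ValueError("fewer than 2 non-constant genes")

    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    n = x.shape[1]
    r = np.corrcoef(x)
    iu, ju = np.triu_indices(len(genes), k=1)
    rv = r[iu, ju]
    pv = _corr_pvalue(rv, n)
    adj = bh_adjust(pv)

    mask = adj < fdr_threshold
    edges = pd.DataFrame(
        {
            "gene_a": genes[iu[mask]],
            "gene_b": genes[ju[mask]],
            "correlation": rv[mask],
            "p": pv[mask],
            "adjusted_p": adj[mask],
        }
    )
    # normalize orientation then sort: |r| desc, lexicographic tie-break
    swap = edges["gene_a"] > edges["gene_b"]
    edges.loc[swap, ["gene_a", "gene_b"]] = edges.loc[
        swap, ["gene_b", "gene_a"]
    ].to_numpy()
    edges["abs_r"] = edges["correlation"].abs()
    edges = (
        edges.sort_values(
            ["abs_r", "gene_a", "gene_b"], ascending=[False, True, True]
        )
        .drop(columns="abs_r")
        .reset_index(drop=True)
    )
    edges.attrs["method"] = method
    return edges


# ---------------------------------------------------------------------------
# planar filtered network

@dataclass
class PlanarNetwork:
    """A planar co-expression graph plus its termination bookkeeping."""

    graph: nx.Graph
    termination_reason: str  # exhausted | edge_cap | all_tested

    @property
    def vertices(self) -> list:
        return list(self.graph.nodes)

    @property
    def edge_cap(self) -> int:
        return max(0, 3 * (self.graph.number_of_nodes() - 2))

    def check_invariants(self) -> None:
        assert self.graph.number_of_edges() <= self.edge_cap
        ok, _ = nx.check_planarity(self.graph)
        assert ok, "PFN is not planar"


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}
        self.size = {x: 1 for x in items}
        self.edges = {x: 0 for x in items}  # edge count per component root

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return ra
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        self.edges[ra] += self.edges[rb]
        return ra


def build_pfn(edges: pd.DataFrame) -> PlanarNetwork:
    """Greedily embed sorted edges subject to planarity; stop at 3(|V|-2).

    ``edges`` must carry ``gene_a, gene_b, correlation`` in embedding order
    (strongest |correlation| first, as produced by
    :func:`screen_correlations`).  The vertex set is all genes appearing in
    the list; the cap 3(|V| - 2) uses that count.
    """
    if len(edges) == 0:
        raise ValueError("empty edge list")
    verts = pd.unique(edges[["gene_a", "gene_b"]].to_numpy().ravel())
    cap = max(0, 3 * (len(verts) - 2))

    G = nx.Graph()
    G.add_nodes_from(verts)
    uf = _UnionFind(verts)
    n_edges = 0
    reason = "all_tested"

    comp_nodes_cache: dict = {}

    for a, b, w in edges[["gene_a", "gene_b", "correlation"]].itertuples(index=False):
        if n_edges >= cap:
            reason = "edge_cap"
            break
        ra, rb = uf.find(a), uf.find(b)
        if ra != rb:
            # joining two planar components by one edge is always planar
            G.add_edge(a, b, weight=w)
            root = uf.union(a, b)
            uf.edges[root] += 1
            n_edges += 1
            comp_nodes_cache.clear()
            continue
        size, ecount = uf.size[ra], uf.edges[ra]
        if size >= 3 and ecount >= 3 * size - 6:
            continue  # component is maximal planar: edge can never fit
        # genuine planarity test, restricted to the candidate's component
        if ra not in comp_nodes_cache:
            comp_nodes_cache[ra] = [v for v in verts if uf.find(v) == ra]
        sub = G.subgraph(comp_nodes_cache[ra]).copy()
        sub.add_edge(a, b)
        ok, _ = nx.check_planarity(sub)
        if ok:
            G.add_edge(a, b, weight=w)
            uf.edges[ra] += 1
            n_edges += 1
    else:
        reason = "all_tested"

    if n_edges >= cap:
        reason = "edge_cap"
    elif reason == "all_tested":
        # saturated: a single component that is maximal planar cannot grow
        roots = {uf.find(v) for v in verts}
        if len(roots) == 1:
            r = roots.pop()
            if uf.size[r] >= 3 and uf.edges[r] >= 3 * uf.size[r] - 6:
                reason = "exhausted"

    return PlanarNetwork(G, reason)


# ---------------------------------------------------------------------------
# compactness (Eq. upsilon = mean SPD / (log |V|)^alpha)

@dataclass(frozen=True)
class CompactnessParams:
    alpha: float
    spd_mean: float
    upsilon: float


def _mean_spd(graph: nx.Graph) -> float:
    """Mean unweighted shortest-path distance over all unordered vertex pairs."""
    nodes = list(graph.nodes)
    n = len(nodes)
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight=None, format="csr")
    dist = shortest_path(adj, method="D", directed=False, unweighted=True)
    if np.isinf(dist).any():
        raise ValueError("graph is disconnected; shortest paths are infinite")
    iu = np.triu_indices(n, k=1)
    return float(dist[iu].mean())


def compactness(net, alpha: float = 1.0, log_base: float = math.e) -> CompactnessParams:
    """Compactness of a connected (sub)graph with at least 3 vertices.

    Smaller upsilon means a more compact topology; ``alpha`` tunes the
    resolution.  Distances are unweighted hop counts; the log base (natural by
    default) only rescales upsilon, never within-``alpha`` comparisons.
    """
    graph = net.graph if isinstance(net, PlanarNetwork) else net
    n = graph.number_of_nodes()
    if n < 3:
        raise ValueError("compactness needs at least 3 vertices")
    spd = _mean_spd(graph)
    upsilon = spd / (math.log(n, log_base) ** alpha)
    return CompactnessParams(alpha=alpha, spd_mean=spd, upsilon=upsilon)


# ---------------------------------------------------------------------------
# multiscale clustering

@dataclass
class Module:
    module_id: str
    parent_id: str | None
    genes: frozenset
    split_alpha: float = float("nan")  # alpha at which the parent split was accepted
    upsilon: float = float("nan")  # compactness at alpha=1 (NaN if undefined)
    modularity_q: float = float("nan")  # Q of this module's accepted child partition


@dataclass
class ModuleHierarchy:
    """Rooted tree of gene modules from recursive modularity splits."""

    modules: dict[str, Module] = field(default_factory=dict)
    root_id: str = "M0"

    def __iter__(self):
        return iter(self.modules.values())

    def __getitem__(self, module_id: str) -> Module:
        return self.modules[module_id]

    def children(self, module_id: str) -> list[Module]:
        return [m for m in self.modules.values() if m.parent_id == module_id]

    def leaves(self) -> list[Module]:
        parents = {m.parent_id for m in self.modules.values() if m.parent_id}
        return [m for m in self.modules.values() if m.module_id not in parents]

    def ancestors(self, module_id: str) -> list[str]:
        out, cur = [], self.modules[module_id].parent_id
        while cur is not None:
            out.append(cur)
            cur = self.modules[cur].parent_id
        return out

    def is_ancestor(self, a: str, b: str) -> bool:
        """True if ``a`` is a (strict) ancestor of ``b``."""
        return a in self.ancestors(b)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                m.module_id,
                m.parent_id,
                len(m.genes),
                m.split_alpha,
                m.upsilon,
                m.modularity_q,
            )
            for m in self.modules.values()
        ]
        return pd.DataFrame(
            rows,
            columns=["module_id", "parent_id", "size", "split_alpha", "upsilon", "Q"],
        )

    def membership(self) -> pd.DataFrame:
        rows = [
            (g, m.module_id) for m in self.modules.values() for g in sorted(m.genes)
        ]
        return pd.DataFrame(rows, columns=["gene", "module_id"])


def _modularity_partition(graph: nx.Graph, seed: int):
    """Modularity-optimizing partition of a graph via multilevel (Louvain)
    agglomeration on |correlation| weights.  Returns (list of vertex sets, Q)."""
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges]
    weights = [abs(d.get("weight", 1.0)) for _, _, d in graph.edges(data=True)]
    g = ig.Graph(n=len(nodes), edges=edges)
    ig.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights=weights if edges else None)
    ig.set_random_number_generator(random)
    q = part.modularity
    groups = [{nodes[i] for i in comm} for comm in part]
    return groups, q


def multiscale_cluster(
    net: PlanarNetwork,
    alpha_grid=(0.5, 1.0, 1.5, 2.0),
    min_module_size: int = 50,
    seed: int = 0,
) -> ModuleHierarchy:
    """Recursive top-down modularity splits gated by the compactness criterion.

    For each parent module the modularity-optimizing partition of its induced
    subgraph is computed; the split is accepted at the smallest ``alpha`` in
    ``alpha_grid`` at which every child (connected, >= 3 vertices) satisfies
    ``upsilon(child, alpha) < upsilon(parent, alpha)``.  Disconnected parents
    are first split into connected components (a free split).  Children below
    ``min_module_size`` are recorded in the hierarchy but not recursed.
    """
    alpha_grid = sorted(alpha_grid)
    graph = net.graph
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")

    hier = ModuleHierarchy()
    counter = [0]

    def new_id() -> str:
        mid = f"M{counter[0]}"
        counter[0] += 1
        return mid

    def upsilon_of(sub: nx.Graph, alpha: float) -> float:
        return _mean_spd(sub) / (math.log(sub.number_of_nodes()) ** alpha)

    def register(genes, parent_id, split_alpha) -> Module:
        sub = graph.subgraph(genes)
        ups = float("nan")
        if len(genes) >= 3 and nx.is_connected(sub):
            ups = upsilon_of(sub, 1.0)
        mod = Module(new_id(), parent_id, frozenset(genes), split_alpha, ups)
        hier.modules[mod.module_id] = mod
        return mod

    root = register(set(graph.nodes), None, float("nan"))
    hier.root_id = root.module_id
    queue = [root]

    while queue:
        parent = queue.pop(0)
        genes = parent.genes
        sub = graph.subgraph(genes)

        if len(genes) >= 2 and not nx.is_connected(sub):
            comps = sorted(nx.connected_components(sub), key=lambda c: (-len(c), sorted(c)))
            for comp in comps:
                child = register(comp, parent.module_id, float("nan"))
                if len(comp) >= min_module_size:
                    queue.append(child)
            continue

        if len(genes) < 4 or not np.isfinite(parent.upsilon):
            continue

        groups, q = _modularity_partition(sub, seed=seed)
        # Louvain communities are usually connected; enforce it regardless
        split_groups = []
        for grp in groups:
            gsub = sub.subgraph(grp)
            split_groups.extend(nx.connected_components(gsub))
        split_groups = sorted(split_groups, key=lambda c: (-len(c), sorted(c)))
        if len(split_groups) <= 1:
            continue  # degenerate single-community partition

        checkable = [g for g in split_groups if len(g) >= 3]
        accepted_alpha = None
        for alpha in alpha_grid:
            ups_parent = _mean_spd(sub) / (math.log(len(genes)) ** alpha)
            if all(
                upsilon_of(sub.subgraph(g), alpha) < ups_parent for g in checkable
            ):
                accepted_alpha = alpha
                break
        if accepted_alpha is None:
            continue

        parent.modularity_q = q
        for grp in split_groups:
            child = register(grp, parent.module_id, accepted_alpha)
            if len(grp) >= min_module_size:
                queue.append(child)

    return hier


# ---------------------------------------------------------------------------
# hub detection

def detect_hubs(
    net: PlanarNetwork,
    hierarchy: ModuleHierarchy,
    n_perm: int = 100,
    p_threshold: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test for module genes with unusually high connectivity.

    The null redistributes the module subnetwork's degrees over its genes by
    label permutation (equivalent to re-embedding a label-permuted correlation
    matrix, which yields an isomorphic planar network).  Empirical p uses the
    add-one rule ``(1 + #{null >= observed}) / (1 + n_perm)`` so p is never 0.

    Returns a table with ``gene, module_id, degree, p, is_hub``.
    """
    if n_perm < 19:
        raise ValueError("n_perm < 19 cannot resolve p < 0.05")
    rng = np.random.default_rng(seed)
    rows = []
    for mod in hierarchy:
        genes = sorted(mod.genes)
        if len(genes) < 3:
            continue
        sub = net.graph.subgraph(genes)
        deg = np.array([sub.degree(g) for g in genes])
        exceed = np.zeros(len(genes), dtype=int)
        for _ in range(n_perm):
            exceed += rng.permutation(deg) >= deg
        pvals = (1 + exceed) / (1 + n_perm)
        for g, d, p in zip(genes, deg, pvals):
            rows.append((g, mod.module_id, int(d), float(p), p < p_threshold))
    return pd.DataFrame(rows, columns=["gene", "module_id", "degree", "p", "is_hub"])


# ---------------------------------------------------------------------------
# neighborhoods

def neighborhood(net, gene, l: int) -> set:
    """Genes whose shortest path to ``gene`` has at most ``l`` edges (incl. itself)."""
    graph = net.graph if isinstance(net, PlanarNetwork) else net
    if gene not in graph:
        raise KeyError(f"gene {gene!r} not in network")
    if l < 0:
        raise ValueError("l must be non-negative")
    return set(nx.single_source_shortest_path_length(graph, gene, cutoff=l))
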
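"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route independent of the package
implementation it checks: brute-force Floyd-Warshall for shortest paths,
exact rational hypergeometric sums for set enrichment, face traversal of a
combinatorial embedding for planarity, explicit partial-likelihood grids for
Cox fits, and label permutation for the log-rank null.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np


def floyd_warshall_mean_spd(graph: nx.Graph) -> float:
    """Mean pairwise shortest-path length by the classic triple loop."""
    nodes = list(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v in graph.edges:
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def verify_planar_embedding(graph: nx.Graph) -> bool:
    """Certify planarity via the embedding: structure check + Euler formula.

    For each connected component with V vertices, E edges and F faces counted
    by traversing the rotation system, a valid planar embedding satisfies
    V - E + F = 2 (an isolated vertex has one face by convention).
    """
    ok, emb = nx.check_planarity(graph)
    if not ok:
        return False
    emb.check_structure()
    for comp in nx.connected_components(graph):
        sub_nodes = set(comp)
        edges = [(u, v) for u, v in graph.edges if u in sub_nodes]
        v_count, e_count = len(sub_nodes), len(edges)
        if e_count == 0:
            faces = 1
        else:
            half_edges = set()
            for u, v in edges:
                half_edges.add((u, v))
                half_edges.add((v, u))
            faces = 0
            visited: set = set()
            for he in sorted(half_edges):
                if he in visited:
                    continue
                faces += 1
                face_nodes = emb.traverse_face(*he)
                for a, b in zip(face_nodes, face_nodes[1:] + face_nodes[:1]):
                    visited.add((a, b))
        if v_count - e_count + faces != 2:
            return False
    return True


def hypergeom_upper_tail(N: int, m: int, n: int, k: int) -> Fraction:
    """Exact P(X >= k) for X ~ Hypergeom(N, n, m) as a rational number."""
    total = comb(N, m)
    acc = Fraction(0)
    for j in range(k, min(m, n) + 1):
        acc += Fraction(comb(n, j) * comb(N - n, m - j), total)
    return acc


def breslow_partial_loglik(beta: float, time, event, x) -> float:
    """Cox partial log-likelihood with Breslow tie handling, written out."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        at_risk = time >= t
        ll += beta * x[dead].sum()
        ll -= dead.sum() * np.log(np.exp(beta * x[at_risk]).sum())
    return ll


def logrank_statistic(time, event, group) -> float:
    """Standard two-group log-rank chi-square statistic, written out."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        deaths = (time == t) & (event == 1)
        n, d = at_risk.sum(), deaths.sum()
        n1 = (at_risk & group).sum()
        o_minus_e += (deaths & group).sum() - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0


def logrank_permutation_p(time, event, group, n_perm: int, seed: int) -> float:
    """Permutation p-value for the log-rank statistic (label shuffles)."""
    rng = np.random.default_rng(seed)
    obs = logrank_statistic(time, event, group)
    group = np.asarray(group, dtype=bool)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(group)
        if logrank_statistic(time, event, perm) >= obs:
            count += 1
    return (1 + count) / (1 + n_perm)
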
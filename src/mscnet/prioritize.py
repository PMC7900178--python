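"""Module filtering, ranking, annotation and regulator nomination.

Modules from the co-expression hierarchy are first filtered by differential
connectivity against a reference cohort (MDC: the ratio of mean intramodule
connectivity between the two cohorts, permutation-tested at FDR < 0.05), then
ranked by Fisher's-exact enrichment of the prognostic signature with
best-per-branch de-duplication, annotated against gene-set collections, and
finally candidate regulators are nominated as the hubs of the top-ranked
modules that are also in the poor-prognosis signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import ExpressionMatrix, GeneSignature
from .network import ModuleHierarchy, bh_adjust

__all__ = [
    "EnrichmentResult",
    "fet_enrichment",
    "mdc_filter",
    "rank_modules",
    "annotate_modules",
    "nominate_regulators",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided (over-representation) Fisher's exact test on a 2x2 overlap."""

    overlap: int  # k
    query_size: int  # m
    target_size: int  # n
    universe_size: int  # N
    p: float
    fold_enrichment: float


def fet_enrichment(query, target, universe) -> EnrichmentResult:
    """Hypergeometric upper-tail p and fold enrichment k*N/(m*n).

    Empty query or target gives the degenerate k=0, p=1 result.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    q = set(query) & universe
    t = set(target) & universe
    m, n, big_n = len(q), len(t), len(universe)
    k = len(q & t)
    if m == 0 or n == 0:
        return EnrichmentResult(0, m, n, big_n, 1.0, 0.0)
    p = float(hypergeom.sf(k - 1, big_n, n, m))
    fe = k * big_n / (m * n)
    return EnrichmentResult(k, m, n, big_n, min(p, 1.0), fe)


# ---------------------------------------------------------------------------
# module differential connectivity

def _abs_corr(values: pd.DataFrame) -> tuple[np.ndarray, dict]:
    x = values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    x = x[sd > 0]
    genes = values.index[sd > 0]
    r = np.abs(np.corrcoef(x))
    np.fill_diagonal(r, 0.0)
    return r, {g: i for i, g in enumerate(genes)}


def _mean_connectivity(r: np.ndarray, idx: list[int]) -> float:
    """Mean over module genes of the summed |r| to the other module genes."""
    block = r[np.ix_(idx, idx)]
    return float(block.sum(axis=1).mean())


def mdc_filter(
    hierarchy: ModuleHierarchy,
    disease_expr,
    reference_expr,
    fdr_threshold: float = 0.05,
    n_perm: int = 100,
    seed: int = 0,
    min_size: int = 3,
) -> pd.DataFrame:
    """Retain modules with significant gain or loss of intramodule connectivity.

    MDC(module) = mean intramodule connectivity in the disease cohort divided
    by the same quantity in the reference cohort, where the connectivity of a
    gene within module M is sum_{j in M, j != i} |r_ij|.  The null permutes
    gene labels within each cohort (equivalently, draws random same-size gene
    sets); the empirical p is two-sided with the add-one rule, and BH FDR is
    applied across modules.

    Returns a table ``module_id, mdc, p, fdr, mdc_retained``; modules with
    genes absent from the reference are skipped with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    dvals = disease_expr.values if isinstance(disease_expr, ExpressionMatrix) else disease_expr
    rvals = reference_expr.values if isinstance(reference_expr, ExpressionMatrix) else reference_expr
    rd, d_index = _abs_corr(dvals)
    rr, r_index = _abs_corr(rvals)
    rng = np.random.default_rng(seed)

    rows = []
    null_cache: dict[int, np.ndarray] = {}
    shared = [g for g in d_index if g in r_index]
    for mod in hierarchy:
        if mod.parent_id is None:
            continue  # the root is the whole network, not a module to filter
        genes = sorted(mod.genes)
        if len(genes) < min_size:
            continue
        if any(g not in r_index or g not in d_index for g in genes):
            warnings.warn(f"module {mod.module_id}: genes missing from a cohort; skipped")
            continue
        di = [d_index[g] for g in genes]
        ri = [r_index[g] for g in genes]
        denom = _mean_connectivity(rr, ri)
        mdc = _mean_connectivity(rd, di) / denom if denom > 0 else np.inf

        size = len(genes)
        if size not in null_cache:
            null = np.empty(n_perm)
            for b in range(n_perm):
                pick = rng.choice(len(shared), size=size, replace=False)
                gset = [shared[i] for i in pick]
                nd = _mean_connectivity(rd, [d_index[g] for g in gset])
                nr = _mean_connectivity(rr, [r_index[g] for g in gset])
                null[b] = nd / nr if nr > 0 else np.inf
            null_cache[size] = null
        null = null_cache[size]
        p_hi = (1 + (null >= mdc).sum()) / (1 + n_perm)
        p_lo = (1 + (null <= mdc).sum()) / (1 + n_perm)
        p = min(1.0, 2.0 * min(p_hi, p_lo))
        rows.append((mod.module_id, mdc, p))

    out = pd.DataFrame(rows, columns=["module_id", "mdc", "p"])
    if len(out):
        out["fdr"] = bh_adjust(out["p"])
        out["mdc_retained"] = out["fdr"] < fdr_threshold
    else:
        out["fdr"] = pd.Series(dtype=float)
        out["mdc_retained"] = pd.Series(dtype=bool)
    return out.set_index("module_id")


# ---------------------------------------------------------------------------
# ranking with branch de-duplication

def rank_modules(
    hierarchy: ModuleHierarchy,
    mdc: pd.DataFrame | None,
    signature: GeneSignature,
    universe,
    min_size: int = 50,
) -> pd.DataFrame:
    """Rank modules by signature enrichment; keep the best module per branch.

    Eligible modules (size >= ``min_size`` and MDC-retained when an MDC table
    is given) are scored by the one-sided FET p of the signature, ranked
    ascending (ties: larger fold enrichment, then smaller module, then id),
    and de-duplicated greedily: walking down the ranking, a module is retained
    iff none of its ancestors or descendants has been retained already, so the
    retained set is an antichain of the hierarchy.
    """
    if len(signature) == 0:
        raise ValueError("empty signature")
    universe = set(universe)
    rows = []
    for mod in hierarchy:
        if mod.parent_id is None:
            continue
        if len(mod.genes) < min_size:
            continue
        if mdc is not None:
            if mod.module_id not in mdc.index or not bool(
                mdc.loc[mod.module_id, "mdc_retained"]
            ):
                continue
        res = fet_enrichment(mod.genes, signature.genes, universe)
        rows.append(
            (mod.module_id, len(mod.genes), res.overlap, res.p, res.fold_enrichment)
        )
    out = pd.DataFrame(
        rows, columns=["module_id", "size", "overlap", "p", "fold_enrichment"]
    )
    if not len(out):
        out["rank"] = pd.Series(dtype=int)
        out["retained"] = pd.Series(dtype=bool)
        return out.set_index("module_id")

    out = out.sort_values(
        ["p", "fold_enrichment", "size", "module_id"],
        ascending=[True, False, True, True],
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)

    retained: list[str] = []
    flags = []
    for mid in out["module_id"]:
        clash = any(
            hierarchy.is_ancestor(mid, other) or hierarchy.is_ancestor(other, mid)
            for other in retained
        )
        flags.append(not clash)
        if not clash:
            retained.append(mid)
    out["retained"] = flags
    return out.set_index("module_id")


# ---------------------------------------------------------------------------
# gene-set annotation

def annotate_modules(
    hierarchy: ModuleHierarchy, collections: dict[str, set], universe
) -> pd.DataFrame:
    """FET of every (module, gene set) pair; BH within each module (cFET).

    Gene sets with no overlap with the universe are skipped.  The correction
    scope (per module, across its tested sets) is recorded in ``attrs``.
    """
    universe = set(universe)
    usable = {
        name: set(gs) & universe
        for name, gs in collections.items()
        if set(gs) & universe
    }
    rows = []
    for mod in hierarchy:
        if mod.parent_id is None:
            continue
        per_mod = []
        for name, gs in usable.items():
            res = fet_enrichment(mod.genes, gs, universe)
            per_mod.append(
                (mod.module_id, name, res.overlap, res.p, res.fold_enrichment)
            )
        if not per_mod:
            continue
        sub = pd.DataFrame(
            per_mod, columns=["module_id", "gene_set", "overlap", "p", "fold_enrichment"]
        )
        sub["cfet_p"] = bh_adjust(sub["p"])
        rows.append(sub)
    if not rows:
        return pd.DataFrame(
            columns=["module_id", "gene_set", "overlap", "p", "fold_enrichment", "cfet_p"]
        )
    out = pd.concat(rows, ignore_index=True)
    out.attrs["correction"] = "BH within module across gene sets"
    return out


# ---------------------------------------------------------------------------
# regulator nomination

def nominate_regulators(
    ranking: pd.DataFrame,
    hubs: pd.DataFrame,
    poor_signature: GeneSignature,
    top_k: int = 10,
    survival_stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Hubs of the top-ranked retained modules intersected with POSG.

    Returns one row per nominated gene with its module of origin and
    within-module connectivity; per-gene survival statistics (Cox and log-rank
    columns) are merged in when provided.
    """
    retained = ranking[ranking["retained"]].sort_values("rank")
    if top_k > len(retained):
        warnings.warn(
            f"top_k={top_k} exceeds {len(retained)} retained modules; using all"
        )
    top = retained.head(top_k)
    top_ids = set(top.index)

    cand = hubs[hubs["is_hub"] & hubs["module_id"].isin(top_ids)]
    cand = cand[cand["gene"].isin(poor_signature.genes)]
    out = cand[["gene", "module_id", "degree", "p"]].rename(
        columns={"degree": "connectivity", "p": "hub_p"}
    )
    if survival_stats is not None and len(out):
        out = out.merge(
            survival_stats, left_on="gene", right_index=True, how="left"
        )
    return out.sort_values(["module_id", "connectivity"], ascending=[True, False]).reset_index(
        drop=True
    )
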
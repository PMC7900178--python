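"""Prognostic and epigenetic gene signatures.

Three signature families feed the module-prioritization stage:

* POSG / GOSG -- genes whose high expression associates with poor / good
  overall survival, by dichotomizing samples at each gene's median expression
  and applying a two-sided log-rank test at p < 0.05.
* Per-gene Cox proportional-hazards coefficients (continuous expression,
  Breslow tie handling) with two-sided Wald p-values.
* MCG (methylation-correlated genes) -- gene/CpG pairs with a significant
  Spearman correlation after Bonferroni correction, classified *cis* when the
  CpG lies within 1.5 kb of the gene's TSS on the same chromosome, *trans*
  otherwise, and signed by the correlation direction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .containers import ExpressionMatrix, GeneSignature, MethylationMatrix, validate_survival_table

__all__ = [
    "median_split_logrank",
    "cox_per_gene",
    "methylation_expression_correlation",
    "common_signature",
]

CIS_WINDOW = 1500  # bp each side of the TSS


def _aligned(expr, surv: pd.DataFrame):
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    surv = validate_survival_table(surv).set_index("sample")
    shared = [s for s in values.columns if s in surv.index]
    if len(shared) < 4:
        raise ValueError("need at least 4 samples shared with the survival table")
    return values[shared], surv.loc[shared]


def median_split_logrank(
    expr, surv: pd.DataFrame, p_threshold: float = 0.05
) -> tuple[GeneSignature, GeneSignature, pd.DataFrame]:
    """Median-dichotomized two-sided log-rank test per gene.

    Samples at or below the gene's median form the "low" group (ties go low).
    Significant genes are directed by which group fares worse: if the
    high-expression group has more deaths than expected under the null
    (positive observed-minus-expected), the gene is POSG (up_poor), else GOSG.

    Returns ``(posg, gosg, table)`` where the table has one row per gene with
    ``logrank_p`` and ``direction``.
    """
    values, sv = _aligned(expr, surv)
    time = sv["time"].to_numpy()
    event = sv["event"].to_numpy()
    if event.sum() == 0:
        raise ValueError("all-censored cohort: log-rank test undefined")

    rows = []
    for gene, row in values.iterrows():
        x = row.to_numpy(dtype=float)
        high = x > np.median(x)
        if high.all() or (~high).all():
            rows.append((gene, np.nan, "none"))
            continue
        res = logrank_test(time[high], time[~high], event[high], event[~high])
        p = float(res.p_value)
        direction = "none"
        if p < p_threshold:
            direction = "up_poor" if _observed_minus_expected(time, event, high) > 0 else "up_good"
        rows.append((gene, p, direction))

    table = pd.DataFrame(rows, columns=["gene", "logrank_p", "direction"]).set_index("gene")
    posg = GeneSignature(
        "POSG",
        frozenset(table.index[table["direction"] == "up_poor"]),
        "up_poor",
        note=f"median-split log-rank p < {p_threshold}",
    )
    gosg = GeneSignature(
        "GOSG",
        frozenset(table.index[table["direction"] == "up_good"]),
        "up_good",
        note=f"median-split log-rank p < {p_threshold}",
    )
    return posg, gosg, table


def _observed_minus_expected(time, event, in_group) -> float:
    """Log-rank O-E for the flagged group; positive means excess deaths."""
    o_minus_e = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        deaths = (time == t) & (event == 1)
        n, d = at_risk.sum(), deaths.sum()
        n1 = (at_risk & in_group).sum()
        o_minus_e += (deaths & in_group).sum() - d * n1 / n
    return o_minus_e


def cox_per_gene(expr, surv: pd.DataFrame) -> pd.DataFrame:
    """Univariate Cox PH fit per gene (Breslow ties, two-sided Wald p).

    Non-convergent genes (monotone likelihood) are flagged with
    ``converged=False`` rather than raising.
    """
    values, sv = _aligned(expr, surv)
    time = sv["time"].to_numpy()
    event = sv["event"].to_numpy()

    rows = []
    for gene, row in values.iterrows():
        x = row.to_numpy(dtype=float)
        if x.std() == 0:
            rows.append((gene, np.nan, np.nan, False))
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = PHReg(time, x[:, None], status=event, ties="breslow").fit(disp=False)
            coef = float(fit.params[0])
            pval = float(fit.pvalues[0])
            ok = np.isfinite(coef) and np.isfinite(pval) and abs(coef) < 50
            rows.append((gene, coef, pval, ok))
        except Exception:
            rows.append((gene, np.nan, np.nan, False))
    return pd.DataFrame(
        rows, columns=["gene", "cox_coef", "cox_p", "converged"]
    ).set_index("gene")


def _spearman_matrix(meth_x: np.ndarray, expr_x: np.ndarray):
    """Spearman rho and two-sided p for every (CpG row, gene row) pair."""
    n = meth_x.shape[1]
    rm = np.apply_along_axis(stats.rankdata, 1, meth_x)
    re = np.apply_along_axis(stats.rankdata, 1, expr_x)
    rm = (rm - rm.mean(axis=1, keepdims=True)) / rm.std(axis=1, keepdims=True)
    re = (re - re.mean(axis=1, keepdims=True)) / re.std(axis=1, keepdims=True)
    rho = rm @ re.T / n
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho * rho))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def methylation_expression_correlation(
    expr,
    meth: MethylationMatrix,
    annot: pd.DataFrame,
    pairing: str = "all",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman CpG-expression correlations with Bonferroni control.

    Parameters
    ----------
    pairing
        ``all`` tests every (gene, CpG) pair; ``per-gene-window`` restricts to
        CpGs within the cis window of each gene's TSS.  The Bonferroni family
        is all tested pairs in the run.
    annot
        Gene annotation with ``chrom``, ``tss_pos`` (0-based) indexed by gene.

    Returns the retained (Bonferroni p < ``alpha``) pairs with ``rho, p,
    bonferroni_p, cls`` (cis/trans) and ``sign``.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    shared = [s for s in values.columns if s in set(meth.sample_ids)]
    if len(shared) < 10:
        raise ValueError("need at least 10 shared samples")

    cpgs_with_coords = meth.values.index.intersection(meth.coords.index)
    dropped = meth.values.index.difference(cpgs_with_coords)
    if len(dropped):
        warnings.warn(f"excluding {len(dropped)} CpG(s) without coordinates")

    genes = [g for g in values.index if g in annot.index]
    ev = values.loc[genes, shared].to_numpy(dtype=float)
    mv = meth.values.loc[cpgs_with_coords, shared].to_numpy(dtype=float)
    gene_chrom = annot.loc[genes, "chrom"].to_numpy()
    gene_tss = annot.loc[genes, "tss_pos"].to_numpy(dtype=int)
    cpg_chrom = meth.coords.loc[cpgs_with_coords, "chrom"].to_numpy()
    cpg_pos = meth.coords.loc[cpgs_with_coords, "pos"].to_numpy(dtype=int)

    is_cis = (cpg_chrom[:, None] == gene_chrom[None, :]) & (
        np.abs(cpg_pos[:, None] - gene_tss[None, :]) <= CIS_WINDOW
    )
    if pairing == "per-gene-window":
        test_mask = is_cis
    elif pairing == "all":
        test_mask = np.ones_like(is_cis, dtype=bool)
    else:
        raise ValueError(f"unknown pairing {pairing!r}")

    rho, p = _spearman_matrix(mv, ev)
    n_tests = int(test_mask.sum())
    if n_tests == 0:
        return pd.DataFrame(
            columns=["cpg", "gene", "rho", "p", "bonferroni_p", "cls", "sign"]
        )
    bonf = np.minimum(p * n_tests, 1.0)

    keep = test_mask & (bonf < alpha)
    ci, gi = np.nonzero(keep)
    out = pd.DataFrame(
        {
            "cpg": np.asarray(cpgs_with_coords)[ci],
            "gene": np.asarray(genes)[gi],
            "rho": rho[ci, gi],
            "p": p[ci, gi],
            "bonferroni_p": bonf[ci, gi],
            "cls": np.where(is_cis[ci, gi], "cis", "trans"),
            "sign": np.where(rho[ci, gi] > 0, "positive", "negative"),
        }
    )
    out.attrs["n_tests"] = n_tests
    return out.sort_values("bonferroni_p").reset_index(drop=True)


def common_signature(a: GeneSignature, b: GeneSignature, name: str | None = None) -> GeneSignature:
    """Intersection of two per-cohort signatures (shared direction required)."""
    if a.direction != b.direction:
        raise ValueError("cannot intersect signatures with different directions")
    return GeneSignature(
        name or f"{a.name}&{b.name}",
        a.genes & b.genes,
        a.direction,
        note=f"intersection of {a.name} and {b.name}",
    )
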
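"""Expression / methylation normalization and covariate removal.

The processing contract is: log2(x + 1) transform followed by quantile
normalization across samples, then per-gene linear-model residualization
against batch and demographic covariates, keeping the fitted intercept so the
baseline expression level is retained.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, MethylationMatrix

__all__ = ["normalize_expression", "quantile_normalize", "residualize", "build_design"]


class DesignError(ValueError):
    """Raised for rank-deficient covariate designs."""


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares the mean quantile vector.

    Ties within a sample receive the mean of the reference quantiles they span
    (average-rank policy), which keeps the procedure deterministic and
    idempotent.
    """
    x = values.to_numpy(dtype=float)
    n_rows = x.shape[0]
    # reference distribution: mean across samples of the sorted columns
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")  # 1..n, ties averaged
        # average rank r maps to mean of ref over the spanned order statistics
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (ref[lo] + ref[hi])
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize_expression(raw: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) then quantile normalization; state becomes ``log_quantile``."""
    if raw.state != "raw":
        raise ValueError(f"expected raw input, got state {raw.state!r}")
    x = raw.values.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative expression values")
    logged = pd.DataFrame(
        np.log2(x + 1.0), index=raw.gene_ids, columns=raw.sample_ids
    )
    return raw.advance(quantile_normalize(logged), "log_quantile")


def build_design(cov: pd.DataFrame, samples) -> pd.DataFrame:
    """Dummy-coded design matrix (intercept first) for the given samples.

    Categorical columns are treatment-coded against the lexicographically
    first level; levels absent among ``samples`` are dropped before the rank
    check.
    """
    cov = cov.set_index("sample") if "sample" in cov.columns else cov
    missing = pd.Index(samples).difference(cov.index)
    if len(missing):
        raise ValueError(f"covariates missing for samples: {list(missing[:5])}")
    cov = cov.loc[samples]
    parts = [pd.Series(1.0, index=cov.index, name="intercept")]
    for col in cov.columns:
        s = cov[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            levels = sorted(s.dropna().unique())
            for lev in levels[1:]:  # first level is the baseline
                parts.append(pd.Series((s == lev).astype(float), name=f"{col}[{lev}]"))
    design = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # name the offending columns for the error message
        keep: list[str] = []
        bad: list[str] = []
        for c in design.columns:
            trial = design[keep + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(c)
            else:
                bad.append(c)
        raise DesignError(f"rank-deficient design; collinear columns: {bad}")
    return design


def residualize(mat, cov: pd.DataFrame):
    """Remove covariate effects per row by OLS, keeping the fitted intercept.

    Accepts an :class:`ExpressionMatrix` or :class:`MethylationMatrix`;
    returns the same type.  Each row ``y`` is regressed on the dummy-coded
    design and replaced by ``intercept + residuals``.
    """
    if isinstance(mat, ExpressionMatrix):
        values, wrap = mat.values, "expr"
    elif isinstance(mat, MethylationMatrix):
        values, wrap = mat.values, "meth"
    else:
        values, wrap = mat, "frame"

    design = build_design(cov, list(values.columns))
    X = design.to_numpy()
    Y = values.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta
    out_vals = (Y - fitted + beta[0][None, :]).T  # residuals + intercept
    out = pd.DataFrame(out_vals, index=values.index, columns=values.columns)

    if wrap == "expr":
        return mat.advance(out, "residualized")
    if wrap == "meth":
        return MethylationMatrix(out, mat.coords)
    return out
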
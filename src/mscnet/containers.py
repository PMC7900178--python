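"""Shared light-weight data containers.

The package works on plain pandas objects wherever possible (genes x samples
DataFrames, tidy tables).  The containers here only add the small amount of
state the pipeline contracts require: normalization state for expression,
genomic coordinates for methylation probes, and named directed gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: allowed normalization states, in order; transitions only move forward
EXPRESSION_STATES = ("raw", "log_quantile", "residualized")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with its normalization state.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    state
        One of ``raw`` (non-negative RPKM/TPM-like), ``log_quantile``
        (log2(x+1) + quantile normalized) or ``residualized``.
    """

    values: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in EXPRESSION_STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate gene or sample identifiers")
        if self.state == "raw" and (np.asarray(self.values) < 0).any():
            raise ValueError("raw expression values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def advance(self, values: pd.DataFrame, state: str) -> "ExpressionMatrix":
        """Return a new matrix in a later normalization state."""
        if EXPRESSION_STATES.index(state) <= EXPRESSION_STATES.index(self.state):
            raise ValueError(
                f"state transition {self.state!r} -> {state!r} is not forward"
            )
        return ExpressionMatrix(values, state=state)


@dataclass
class MethylationMatrix:
    """CpG x samples M-value matrix with probe genomic coordinates.

    ``coords`` is indexed by CpG id with columns ``chrom`` and ``pos``
    (0-based).  Every probe in ``values`` must have coordinates.
    """

    values: pd.DataFrame
    coords: pd.DataFrame

    def __post_init__(self) -> None:
        missing = self.values.index.difference(self.coords.index)
        if len(missing):
            raise ValueError(f"CpGs without coordinates: {list(missing[:5])}...")

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class GeneSignature:
    """Named, optionally directed gene set (e.g. POSG / GOSG / siRNA DEGs)."""

    name: str
    genes: frozenset[str]
    direction: str = "none"  # up_poor | up_good | none
    note: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("up_poor", "up_good", "none"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.genes)


def validate_survival_table(surv: pd.DataFrame) -> pd.DataFrame:
    """Check a (sample, time, event) table and return it with clean dtypes."""
    required = {"sample", "time", "event"}
    if not required.issubset(surv.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    if surv["sample"].duplicated().any():
        raise ValueError("duplicate samples in survival table")
    out = surv.copy()
    out["time"] = out["time"].astype(float)
    out["event"] = out["event"].astype(int)
    if not np.isfinite(out["time"]).all() or (out["time"] < 0).any():
        raise ValueError("survival times must be finite and non-negative")
    if not out["event"].isin((0, 1)).all():
        raise ValueError("events must be 0/1")
    return out
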
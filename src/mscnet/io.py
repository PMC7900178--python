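"""Readers and writers for the plain-text interchange formats.

Expression / methylation matrices travel as TSV with genes (or CpGs) in rows
and a header of sample ids; survival and covariate tables as tidy TSV;
single-cell matrices as TSV or MatrixMarket triplets with side files of gene
and cell ids; gene sets as GMT; planted truth as JSON; configs as YAML.
"""

from __future__ import annotations

import io as _io
import os

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio, sparse

from .containers import ExpressionMatrix, MethylationMatrix, validate_survival_table
from .simulate import CellTypeSpec, ModuleSpec, SimulationConfig

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_survival_tsv",
    "write_survival_tsv",
    "read_covariates_tsv",
    "read_methylation",
    "write_methylation",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_gmt",
    "write_gmt",
    "read_sc_mtx",
    "write_sc_mtx",
    "load_config",
]


def read_expression_tsv(path, state: str = "raw") -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values, state=state)


def write_expression_tsv(expr: ExpressionMatrix | pd.DataFrame, path) -> None:
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    values.to_csv(path, sep="\t")


def read_survival_tsv(path) -> pd.DataFrame:
    return validate_survival_table(pd.read_csv(path, sep="\t"))


def write_survival_tsv(surv: pd.DataFrame, path) -> None:
    validate_survival_table(surv).to_csv(path, sep="\t", index=False)


def read_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_methylation(values_path, coords_path) -> MethylationMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    coords = pd.read_csv(
        coords_path, sep="\t", header=None, names=["chrom", "pos", "cpg_id"]
    ).set_index("cpg_id")
    return MethylationMatrix(values, coords)


def write_methylation(meth: MethylationMatrix, values_path, coords_path) -> None:
    meth.values.to_csv(values_path, sep="\t")
    meth.coords.reset_index()[["chrom", "pos", "cpg_id"]].to_csv(
        coords_path, sep="\t", header=False, index=False
    )


def read_gene_annotation(path) -> pd.DataFrame:
    """BED-like annotation: chrom, tss_pos, strand, gene_id."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "tss_pos", "strand", "gene_id"]
    ).set_index("gene_id")[["chrom", "tss_pos", "strand"]]


def write_gene_annotation(annot: pd.DataFrame, path) -> None:
    annot.reset_index()[["chrom", "tss_pos", "strand", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gmt(path) -> dict[str, set]:
    """GMT gene sets: name, description, genes... (tab-separated)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(g for g in parts[2:] if g)
    return out


def write_gmt(collections: dict[str, set], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(collections):
            genes = "\t".join(sorted(collections[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_sc_mtx(mtx_path, genes_path, cells_path) -> pd.DataFrame:
    mat = spio.mmread(mtx_path)
    genes = pd.read_csv(genes_path, header=None)[0].tolist()
    cells = pd.read_csv(cells_path, header=None)[0].tolist()
    return pd.DataFrame(np.asarray(mat.todense()), index=genes, columns=cells)


def write_sc_mtx(values: pd.DataFrame, mtx_path, genes_path, cells_path) -> None:
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(values.to_numpy()))
    pd.Series(values.index).to_csv(genes_path, header=False, index=False)
    pd.Series(values.columns).to_csv(cells_path, header=False, index=False)


def load_config(path) -> SimulationConfig:
    """SimulationConfig from YAML; nested specs given as lists of mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "module_spec" in raw:
        raw["module_spec"] = tuple(ModuleSpec(**m) for m in raw["module_spec"])
    if "cell_type_spec" in raw:
        specs = []
        for c in raw["cell_type_spec"]:
            if c.get("marker_genes") is not None:
                c["marker_genes"] = tuple(c["marker_genes"])
            specs.append(CellTypeSpec(**c))
        raw["cell_type_spec"] = tuple(specs)
    if "hazard_spec" in raw:
        raw["hazard_spec"] = tuple((h["module_id"], float(h["log_hazard_ratio"])) for h in raw["hazard_spec"])
    return SimulationConfig(**raw)
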
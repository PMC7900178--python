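"""Synthetic cohort generators with planted, machine-readable ground truth.

Every downstream stage of the pipeline makes structural assumptions about its
input: hierarchically nested blocks of co-expressed genes, proportional-hazards
survival effects driven by module eigengenes, CpG methylation coupled to gene
expression in cis (within +/-1.5 kb of the TSS) or in trans, and single-cell
populations defined by marker genes over a shared background.  The generators
here plant exactly those structures and emit the truth alongside, so parameter
recovery can be measured.

Construction notes
------------------
* Co-expressed blocks use a latent-factor (compound-symmetric) construction:
  a gene in a module with within-correlation ``r`` is
  ``sqrt(r) * factor + sqrt(1 - r) * noise`` on the latent z-scale, so any two
  members correlate at ``r``.  A child module adds its own factor on top of the
  parent chain, which makes nested blocks strictly more correlated than their
  parents -- the gradient the compactness criterion of the multiscale
  clustering must detect.
* One gene per module (by default) is planted as a hub by giving it a loading
  of ``hub_loading`` on the module factor: its correlation with every member,
  ``sqrt(hub_loading * r)``, exceeds the member-member correlation ``r``, so
  its edges are embedded first and it acquires a star-like neighborhood.
* The z-scale is mapped to an RPKM-like scale by ``2**(mu_g + z) - 1`` with
  gene baselines ``mu_g`` drawn from [4, 8]; the pipeline's log2(x+1)
  normalization approximately inverts this, preserving the planted Pearson
  structure on the analysis scale.
* Survival times are exponential with hazard ``b0 * exp(sum beta_m * g_m)``
  where ``g_m`` is the unit-variance module eigengene, censored
  administratively at a configurable quantile of the drawn times.
* Planted CpG couplings use a Gaussian copula on the gene's normal scores with
  Pearson ``2 sin(pi * rho_S / 6)`` so that the realized *Spearman*
  correlation targets ``coupling_rho``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MethylationMatrix

__all__ = [
    "ModuleSpec",
    "CellTypeSpec",
    "SimulationConfig",
    "PlantedTruth",
    "generate_bulk_cohort",
    "generate_methylation",
    "generate_single_cell",
    "generate_reference_cohort",
    "default_config",
]

N_CHROMS = 5
GENE_SPACING = 10_000  # bp between successive TSSs on a chromosome


class ConfigurationError(ValueError):
    """Raised for infeasible or inconsistent simulation configurations."""


@dataclass(frozen=True)
class ModuleSpec:
    module_id: str
    parent_id: str | None
    gene_count: int
    within_correlation: float


@dataclass(frozen=True)
class CellTypeSpec:
    type_name: str
    cell_count: int
    marker_genes: tuple[str, ...] | None = None  # None -> assigned by generator
    marker_fold: float = 5.0


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults matching the default
    study conditions (4 planted 50-gene modules at within-r 0.7, n=200 samples,
    a unit log-hazard on one module eigengene, CpG couplings at Spearman 0.8,
    and 3 cell types x 100 cells with 5-fold markers)."""

    n_genes: int = 400
    n_samples: int = 200
    module_spec: tuple[ModuleSpec, ...] = (
        ModuleSpec("M1", None, 50, 0.7),
        ModuleSpec("M2", None, 50, 0.7),
        ModuleSpec("M3", None, 50, 0.7),
        ModuleSpec("M4", None, 50, 0.7),
    )
    hazard_spec: tuple[tuple[str, float], ...] = (("M1", 1.0),)
    hubs_per_module: int = 1
    hub_loading: float = 0.95
    baseline_hazard: float = 0.1
    censor_quantile: float = 0.8
    batch_effect: float = 0.5
    age_effect: float = 0.01
    n_cpgs: int = 200
    n_coupled_cpgs: int = 40
    cis_fraction: float = 0.5
    coupling_rho: float = 0.8
    n_cells: int = 300
    cell_type_spec: tuple[CellTypeSpec, ...] = (
        CellTypeSpec("TypeA", 100),
        CellTypeSpec("TypeB", 100),
        CellTypeSpec("TypeC", 100),
    )
    markers_per_type: int = 20
    sc_noise_sd: float = 1.0
    dropout_base: float = 0.6
    dropout_scale: float = 5.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.cis_fraction, self.censor_quantile):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("fractions must lie in [0, 1]")
        if not 0.0 <= self.coupling_rho <= 1.0:
            raise ConfigurationError("coupling_rho must lie in [0, 1]")
        if sum(m.gene_count for m in self.module_spec) > self.n_genes:
            raise ConfigurationError("module gene counts exceed n_genes")
        ids = [m.module_id for m in self.module_spec]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate module ids")
        known = set(ids)
        for m in self.module_spec:
            if m.parent_id is not None and m.parent_id not in known:
                raise ConfigurationError(f"unknown parent {m.parent_id!r}")
            if not 0.0 <= m.within_correlation <= 1.0:
                raise ConfigurationError("within_correlation must lie in [0, 1]")
        for mid, _ in self.hazard_spec:
            if mid not in known:
                raise ConfigurationError(f"hazard on unknown module {mid!r}")
        if self.n_coupled_cpgs > self.n_cpgs:
            raise ConfigurationError("n_cpgs < number of requested couplings")


@dataclass
class PlantedTruth:
    """Ground truth emitted with every generated dataset."""

    module_chain: dict[str, list[str]] = field(default_factory=dict)  # gene -> [root..leaf]
    hubs: dict[str, str] = field(default_factory=dict)  # gene -> module id
    survival_direction: dict[str, str] = field(default_factory=dict)  # gene -> +|-|0
    cpg_map: dict[str, dict] = field(default_factory=dict)  # cpg -> {gene, cls, sign}
    cell_types: dict[str, str] = field(default_factory=dict)  # cell -> type
    markers: dict[str, list[str]] = field(default_factory=dict)  # type -> genes
    covariate_effects: dict[str, float] = field(default_factory=dict)

    def leaf_module(self, gene: str) -> str | None:
        chain = self.module_chain.get(gene)
        return chain[-1] if chain else None

    def module_genes(self, module_id: str) -> set[str]:
        return {g for g, chain in self.module_chain.items() if module_id in chain}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def default_config(**overrides) -> SimulationConfig:
    """The default study conditions, with keyword overrides."""
    return SimulationConfig(**overrides)


# ---------------------------------------------------------------------------
# helpers

def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _gene_annotation(genes: list[str]) -> pd.DataFrame:
    """Synthetic genome: genes round-robin over chromosomes, evenly spaced TSSs."""
    rows = []
    for i, g in enumerate(genes):
        chrom = f"chr{i % N_CHROMS + 1}"
        tss = GENE_SPACING * (i // N_CHROMS + 1)
        strand = "+" if (i // N_CHROMS) % 2 == 0 else "-"
        rows.append((g, chrom, tss, strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss_pos", "strand"]).set_index(
        "gene_id"
    )


def _module_chains(spec) -> dict[str, list[str]]:
    """module id -> [root, ..., self] resolved from parent pointers."""
    parent = {m.module_id: m.parent_id for m in spec}
    chains: dict[str, list[str]] = {}
    for mid in parent:
        chain, cur = [], mid
        while cur is not None:
            chain.append(cur)
            cur = parent[cur]
        chains[mid] = chain[::-1]
    return chains


def _assign_module_genes(config: SimulationConfig) -> dict[str, list[str]]:
    """Deterministic gene budget: modules take genes in spec order."""
    genes = _gene_ids(config.n_genes)
    out, cursor = {}, 0
    for m in config.module_spec:
        out[m.module_id] = genes[cursor : cursor + m.gene_count]
        cursor += m.gene_count
    return out


def _latent_z(config: SimulationConfig, rng: np.random.Generator,
              rewired: set[str] | None = None):
    """Latent gene x sample z-scores plus module eigengenes and truth maps.

    ``rewired`` modules have their correlation structure destroyed (genes
    become independent noise) while everything else is drawn identically in
    distribution.
    """
    rewired = rewired or set()
    n, p = config.n_samples, config.n_genes
    genes = _gene_ids(p)
    chains = _module_chains(config.module_spec)
    direct = _assign_module_genes(config)
    rvals = {m.module_id: m.within_correlation for m in config.module_spec}

    factors = {mid: rng.standard_normal(n) for mid in chains}
    z = rng.standard_normal((p, n))  # background / idiosyncratic noise
    z_index = {g: i for i, g in enumerate(genes)}

    truth = PlantedTruth()
    eigengenes: dict[str, np.ndarray] = {}

    for mid, chain in chains.items():
        # cumulative loadings along the ancestor chain
        r_chain = [rvals[c] for c in chain]
        for a, b in zip(r_chain, r_chain[1:]):
            if b <= a:
                raise ConfigurationError(
                    f"child correlation must exceed parent along chain {chain}"
                )
        r_total = r_chain[-1]
        combined = np.zeros(n)
        prev = 0.0
        for cid, r in zip(chain, r_chain):
            combined += np.sqrt(r - prev) * factors[cid]
            prev = r
        if r_total > 0:
            eigengene = combined / np.sqrt(r_total)  # unit variance
        else:
            eigengene = factors[mid].copy()
        eigengenes[mid] = eigengene

        member_genes = direct[mid]
        is_rewired = bool(set(chain) & rewired)
        for j, g in enumerate(member_genes):
            truth.module_chain[g] = list(chain)
            if is_rewired or r_total == 0:
                continue  # stays pure noise
            i = z_index[g]
            if j < config.hubs_per_module:
                load = config.hub_loading
                truth.hubs[g] = mid
                z[i] = np.sqrt(load) * eigengene + np.sqrt(1 - load) * z[i]
            else:
                z[i] = combined + np.sqrt(1 - r_total) * z[i]

    hazard = dict(config.hazard_spec)
    for g, chain in truth.module_chain.items():
        beta = sum(hazard.get(mid, 0.0) for mid in chain)
        truth.survival_direction[g] = "+" if beta > 0 else ("-" if beta < 0 else "0")
    for g in genes:
        truth.survival_direction.setdefault(g, "0")

    return genes, z * config.noise_sd, eigengenes, truth


def _to_rpkm(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    mu = rng.uniform(4.0, 8.0, size=z.shape[0])[:, None]
    return np.maximum(np.exp2(mu + z) - 1.0, 0.0)


# ---------------------------------------------------------------------------
# generators

def generate_bulk_cohort(config: SimulationConfig):
    """Generate an RPKM-like bulk cohort with planted module/hazard structure.

    Returns ``(expression, survival, covariates, truth)``.
    """
    rng = np.random.default_rng(config.seed)
    genes, z, eigengenes, truth = _latent_z(config, rng)
    samples = [f"S{i:04d}" for i in range(config.n_samples)]

    # covariates with additive effects on the latent scale
    batch = rng.choice(["batchA", "batchB"], size=config.n_samples)
    age = rng.uniform(40.0, 80.0, size=config.n_samples)
    effect = config.batch_effect * (batch == "batchB") + config.age_effect * (age - 60.0)
    truth.covariate_effects = {
        "batch_batchB": config.batch_effect,
        "age_per_year": config.age_effect,
    }

    rpkm = _to_rpkm(z + effect[None, :], rng)
    expr = ExpressionMatrix(
        pd.DataFrame(rpkm, index=genes, columns=samples), state="raw"
    )

    # proportional-hazards survival on module eigengenes
    hazard = dict(config.hazard_spec)
    eta = np.zeros(config.n_samples)
    for mid, beta in hazard.items():
        eta += beta * eigengenes[mid]
    lam = config.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / lam)
    censor = np.quantile(t_event, config.censor_quantile)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    surv = pd.DataFrame({"sample": samples, "time": time, "event": event})

    cov = pd.DataFrame({"sample": samples, "batch": batch, "age": age})
    return expr, surv, cov, truth


def generate_methylation(config: SimulationConfig, bulk: ExpressionMatrix):
    """Generate an M-value matrix with planted cis/trans CpG-gene couplings.

    Coupled CpGs hit ``coupling_rho`` in |Spearman| against their target gene;
    cis probes land within +/-1500 bp of the target's TSS, trans probes on a
    different chromosome.  Returns ``(methylation, gene_annotation, truth)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    genes = list(bulk.gene_ids)
    samples = list(bulk.sample_ids)
    n = len(samples)
    annot = _gene_annotation(genes)

    n_coupled = config.n_coupled_cpgs
    n_cis = int(round(config.cis_fraction * n_coupled))
    target_genes = rng.choice(genes, size=n_coupled, replace=False)

    # normal scores of the target genes' expression (rank-preserving)
    expr = bulk.values.to_numpy()
    from scipy.stats import rankdata, norm

    rho_p = 2.0 * np.sin(np.pi * config.coupling_rho / 6.0)

    cpg_ids = [f"cg{i:06d}" for i in range(config.n_cpgs)]
    m_values = rng.standard_normal((config.n_cpgs, n))
    coords_rows = []
    truth = PlantedTruth()
    gene_pos = {g: i for i, g in enumerate(genes)}

    for idx, g in enumerate(target_genes):
        x = expr[gene_pos[g]]
        u = norm.ppf((rankdata(x) - 0.5) / n)
        sign = 1 if rng.random() < 0.5 else -1
        noise = rng.standard_normal(n)
        m_values[idx] = sign * (rho_p * u + np.sqrt(1 - rho_p**2) * noise)
        cls = "cis" if idx < n_cis else "trans"
        chrom, tss = annot.loc[g, "chrom"], int(annot.loc[g, "tss_pos"])
        if cls == "cis":
            pos = max(0, tss + int(rng.integers(-1500, 1501)))
        else:
            other = [f"chr{c}" for c in range(1, N_CHROMS + 1) if f"chr{c}" != chrom]
            chrom = other[int(rng.integers(len(other)))]
            pos = int(rng.integers(0, GENE_SPACING * (len(genes) // N_CHROMS + 2)))
        coords_rows.append((cpg_ids[idx], chrom, pos))
        truth.cpg_map[cpg_ids[idx]] = {
            "gene": g,
            "cls": cls,
            "sign": "positive" if sign > 0 else "negative",
        }

    # uncoupled probes scattered uniformly over the synthetic genome
    for idx in range(n_coupled, config.n_cpgs):
        chrom = f"chr{int(rng.integers(1, N_CHROMS + 1))}"
        pos = int(rng.integers(0, GENE_SPACING * (len(genes) // N_CHROMS + 2)))
        coords_rows.append((cpg_ids[idx], chrom, pos))

    coords = pd.DataFrame(coords_rows, columns=["cpg_id", "chrom", "pos"]).set_index(
        "cpg_id"
    )
    meth = MethylationMatrix(
        pd.DataFrame(m_values, index=cpg_ids, columns=samples), coords
    )
    return meth, annot, truth


def generate_single_cell(config: SimulationConfig):
    """Generate a TPM-like genes x cells matrix with marker-defined types.

    Each cell's expression is background plus a ``marker_fold`` elevation on
    its type's markers, with per-gene Bernoulli dropout whose rate decreases
    with mean expression.  Returns ``(values, truth)`` where ``values`` is a
    genes x cells DataFrame on the linear TPM-like scale.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    genes = _gene_ids(config.n_genes)
    gene_set = set(genes)

    # resolve markers: explicit lists validated, otherwise disjoint auto blocks
    truth = PlantedTruth()
    auto_cursor = 0
    resolved: list[tuple[CellTypeSpec, list[str]]] = []
    for spec in config.cell_type_spec:
        if spec.marker_genes is not None:
            missing = set(spec.marker_genes) - gene_set
            if missing:
                raise ConfigurationError(f"marker genes not in universe: {missing}")
            markers = list(spec.marker_genes)
        else:
            markers = genes[auto_cursor : auto_cursor + config.markers_per_type]
            auto_cursor += config.markers_per_type
            if len(markers) < config.markers_per_type:
                raise ConfigurationError("gene universe too small for auto markers")
        resolved.append((spec, markers))
        truth.markers[spec.type_name] = markers

    total_cells = sum(s.cell_count for s, _ in resolved)
    cells = [f"C{i:05d}" for i in range(total_cells)]
    base = rng.uniform(0.5, 2.0, size=config.n_genes)  # per-gene log2 baseline

    log_x = np.empty((config.n_genes, total_cells))
    gene_index = {g: i for i, g in enumerate(genes)}
    cursor = 0
    for spec, markers in resolved:
        block = slice(cursor, cursor + spec.cell_count)
        log_x[:, block] = base[:, None] + config.sc_noise_sd * rng.standard_normal(
            (config.n_genes, spec.cell_count)
        )
        if spec.marker_fold != 1.0:
            rows = [gene_index[g] for g in markers]
            log_x[rows, block] += np.log2(spec.marker_fold)
        for c in cells[block]:
            truth.cell_types[c] = spec.type_name
        cursor += spec.cell_count

    tpm = np.maximum(np.exp2(log_x) - 1.0, 0.0)
    # per-gene dropout, rarer for highly expressed genes
    mean_expr = tpm.mean(axis=1)
    rate = config.dropout_base * np.exp(-mean_expr / config.dropout_scale)
    keep = rng.random(tpm.shape) >= rate[:, None]
    tpm *= keep

    values = pd.DataFrame(tpm, index=genes, columns=cells)
    return values, truth


def generate_reference_cohort(
    config: SimulationConfig, truth: PlantedTruth, rewired_modules: set[str]
) -> ExpressionMatrix:
    """Fresh draw of the cohort with listed modules' co-expression destroyed.

    Used as the "reference tissue" input of the differential-connectivity
    filter: rewired modules keep their genes but lose all within-module
    correlation; other modules are drawn from the identical model.
    """
    known = {m.module_id for m in config.module_spec}
    unknown = set(rewired_modules) - known
    if unknown:
        raise KeyError(f"unknown module ids: {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    genes, z, _, _ = _latent_z(config, rng, rewired=set(rewired_modules))
    samples = [f"R{i:04d}" for i in range(config.n_samples)]
    rpkm = _to_rpkm(z, rng)
    return ExpressionMatrix(pd.DataFrame(rpkm, index=genes, columns=samples), state="raw")
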
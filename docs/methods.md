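# Methods

`mscnet` implements an integrative multiscale co-expression network pipeline:
a planar filtered network (PFN) is built from pairwise correlations,
decomposed into a hierarchy of modules by compactness-gated modularity
splits, and integrated with survival, methylation, and single-cell evidence
to rank modules and nominate candidate regulator genes.  Everything is
exercised on synthetic cohorts with planted ground truth, so every stage's
recovery can be measured.

## Network construction

**Correlation screen.** All gene pairs are tested (Pearson by default,
Spearman for single-cell data); two-sided p-values come from the
t-distribution of the correlation coefficient; Benjamini–Hochberg control is
applied over all pairs and pairs with adjusted p < 0.05 are kept, sorted by
|r| descending.  Equal |r| values are broken lexicographically by gene pair,
which makes the embedding deterministic (otherwise a K5 of equal weights
would have an ambiguous result).  Constant genes are excluded with a
warning, since their correlations are undefined.

**Planar filtered network.** Sorted pairs are embedded greedily: an edge is
kept iff the accumulated graph stays planar, and the process stops when the
planar edge cap 3(|V| − 2) is reached or the list is exhausted.  Planarity
is tested combinatorially (networkx's left–right test); embedding on the
sphere and combinatorial planarity select the same edge set.  Two exact
shortcuts keep the loop fast without changing the result: an edge joining
two distinct planar components is accepted without a test (a one-edge join
of planar graphs is planar), and an edge inside a component that already
holds 3n − 6 edges is rejected without a test (the component is maximal
planar).  The planarity test itself runs on the candidate's connected
component only.

**Compactness.** For a connected subgraph with at least three vertices,

    υ(G, α) = mean shortest-path distance / (log |V|)^α

with unweighted hop distances and the natural log (the log base rescales υ
but never changes a comparison at fixed α; it is exposed as an option).
Smaller υ means a more compact topology, and α tunes the resolution.

**Multiscale clustering.** Each parent module's induced subgraph is
partitioned by multilevel (Louvain-style) modularity optimization on
|correlation| weights with a fixed seed; vertex order is canonicalized so
the result is invariant to gene input order.  The split is accepted at the
smallest α in the grid (default 0.5, 1.0, 1.5, 2.0) at which **every** child
is more compact than the parent, υ(child, α) < υ(parent, α).  Decisions for
the cases the rule leaves open: disconnected parents are first split into
connected components (a free split with no α); communities that come out
disconnected are split into components before the check; children with
fewer than three vertices cannot carry a υ value and are exempt from the
comparison.  Children smaller than `min_module_size` are recorded in the
hierarchy but not recursed, and are excluded from downstream ranking by that
same size floor.  The default floor is 50 genes (synthetic tests use 10, as
their planted modules are smaller).

**Hubs.** A module gene is a hub when its within-module degree exceeds the
degree distribution of label-permuted networks at p < 0.05, with the
add-one empirical rule p = (1 + #{null ≥ observed}) / (1 + n_perm), which
can never return zero.  Permuting the gene labels of the correlation matrix
and re-embedding yields a network isomorphic to the original (the sorted
edge list is unchanged up to renaming), so the null is realized directly by
permuting vertex labels of the module subnetwork — equivalent and far
cheaper than re-embedding.  At least 19 permutations are required to be able
to resolve p < 0.05.

## Signatures

**Survival.** For each gene, samples are dichotomized at the median (ties go
to the low group, a deterministic choice) and compared by a two-sided
log-rank test (lifelines); genes at p < 0.05 are directed by the sign of the
high-expression group's observed-minus-expected deaths: positive → POSG
(up in poor prognosis), negative → GOSG.  POSG and GOSG are disjoint by
construction, and the median split depends only on ranks, so the p-value is
invariant to monotone transformations of expression.  Per-gene Cox
proportional-hazards fits (statsmodels PHReg, Breslow ties, two-sided Wald
p) are reported alongside; genes with monotone likelihoods are flagged as
non-converged rather than raising.  Signature membership is gated on the
log-rank p; the Cox columns are reported for reference.  A set-intersection
utility combines signatures across cohorts.

**Methylation (MCG).** Spearman correlation of every tested (gene, CpG)
pair, Bonferroni-corrected over all tested pairs in the run (global family
by default; a per-gene-window pairing is available).  Retained pairs are
classified *cis* iff the CpG lies on the same chromosome within a closed
±1500 bp window of the gene's TSS, else *trans*, and signed by the
correlation direction.  Classification is a pure function of coordinates:
permuting samples changes ρ and p but never the cis/trans label.

## Module prioritization

**Enrichment.** One-sided (over-representation) hypergeometric p with fold
enrichment FE = k·N/(m·n).  Module annotation against gene-set collections
corrects with BH within each module across its tested sets ("cFET"); the
correction scope is recorded in the output metadata.

**Differential connectivity (MDC).** MDC(module) is the ratio of mean
intramodule connectivity between the disease and reference cohorts, where a
gene's connectivity within module M is the sum of |r| to the other module
genes.  The null redistributes module membership by drawing random same-size
gene sets (equivalently, permuting gene labels) within each cohort; the
empirical p is two-sided with the add-one rule and BH FDR is applied across
modules.  MDC is scale-invariant (correlations are), and a module tested
against its own cohort gives exactly 1.  Note the resolution constraint:
with n_perm permutations the smallest two-sided p is 2/(n_perm + 1), so
n_perm = 500 is used in the worked analyses — 100 permutations cannot
survive BH across a dozen modules.

**Ranking and de-duplication.** Eligible modules (size floor, MDC-retained)
are ranked by signature-enrichment p (ties: larger FE, then smaller module,
then id).  Walking down the ranking, a module is retained iff none of its
ancestors or descendants is already retained, so the retained set is an
antichain of the hierarchy — one best module per branch.

**Regulator nomination.** The hubs of the top-k retained modules,
intersected with the poor-prognosis signature, annotated with module of
origin, connectivity and (optionally) the per-gene survival statistics.

## Single-cell integration

Cells are embedded in the first 10 principal components of log2(TPM+1)
(deterministic full SVD), joined into a union-symmetrized kNN graph
(union keeps the graph connected at small k), and clustered by walktrap
(4-step walks, the conventional default).  The neighborhood size k is chosen
over k ∈ [2, ⌊√N_c⌋] by the elbow — maximum perpendicular distance to the
chord — of the curve of Shannon entropy of cluster-size proportions; a flat
curve falls back to the smallest k with a warning.  Cluster markers come
from Welch t-tests on the log scale (a self-contained two-group location
test) with BH per cluster; a marker needs FDR < 0.05 **and** a linear-scale
fold strictly above 1.2 — a fold of exactly 1.2 is excluded.  Cell types are
predicted by a decision tree over marker-gene features (depth capped at
#types + 2, fixed seed) trained on labeled reference cells, then refined by
the majority type among each cell's k nearest neighbors with a
hypergeometric tie-break; k_refine = 0 reproduces the tree output.
Gene/cell-type specificity tests the TPM > 0 expressing-cell set of each
gene against each type's cells by FET with global BH — assignments depend
only on the support, hence are invariant to rescaling.  Per-cluster networks
drop genes expressed in fewer than 20 cells (a gene in exactly 19 cells is
dropped; in 20, kept) and reuse the Spearman screen → PFN → multiscale
clustering stack.  Bulk and single-cell modules are conserved when the
Bonferroni-corrected FET p over all tested pairs is < 0.05, FE > 2
(strictly), and the overlap covers ≥ 30% of the genes of each module.
Perturbation signatures validate a gene's local structure when the
BH-corrected FET p of the signature in the gene's l-layer neighborhood is
< 0.05; neighborhoods covering more than 10% of the network are not tested.

## Synthetic data

The generators plant exactly the structures the pipeline assumes.

* **Bulk expression**: a latent-factor construction gives compound-symmetric
  blocks — a module gene is √r·factor + √(1−r)·noise, so any two members
  correlate at r; a child module adds its own factor on top of its parent's
  chain, making nested blocks strictly more correlated.  One gene per module
  (default) is a planted hub with loading 0.95 on the module factor; its
  correlation to every member, √(0.95·r), exceeds r, so its edges embed
  first and it acquires the star-like neighborhood the hub test and the
  compactness criterion expect.  z-scores map to an RPKM-like scale via
  2^(μ_g+z) − 1 with per-gene baselines μ_g ∈ [4, 8]; log2(x+1)
  approximately inverts this, so the planted Pearson structure survives on
  the analysis scale.  Batch (two levels, +0.5 latent shift) and age (+0.01
  per year) act additively and are recorded in the truth.
* **Survival**: exponential baseline hazard 0.1 scaled by exp(Σ β_m·g_m) on
  unit-variance module eigengenes, administratively censored at the 0.8
  quantile of event times (≈ 20% censoring).  Default effect: β = 1.0 on one
  module.
* **Methylation**: coupled CpGs are Gaussian-copula draws against the target
  gene's normal scores with Pearson 2·sin(π·ρ_S/6), so the realized
  *Spearman* correlation targets `coupling_rho` (0.8 by default); cis probes
  land uniformly within ±1500 bp of the target's TSS on a synthetic genome
  (5 chromosomes, evenly spaced 0-based TSSs), trans probes on another
  chromosome.
* **Single cells**: log-scale background per gene plus log2(marker_fold)
  elevation on the cell's type markers, mapped to a linear TPM-like scale,
  with per-gene Bernoulli dropout whose rate 0.6·exp(−mean/5) decreases with
  mean expression — giving the zero-inflation the TPM > 0 specificity test
  relies on.  Defaults: 3 types × 100 cells, 20 markers each, fold 5.
* **Reference cohort**: a fresh draw from the same model with the listed
  modules' correlation destroyed (genes become independent noise) — the
  differential-connectivity contrast.

What the generators do **not** emulate: read-level noise, gene-length
effects, copy-number or mutational structure, realistic library-size
variation, batch-by-gene interactions, doublets, or cell-cycle structure.
Passing tests therefore demonstrate correctness of the algorithms under the
stated statistical model, not robustness to every artifact of real data.

## Problem sizes and numerical choices

The worked analyses and tests use deliberately compact problem sizes chosen
to exercise every code path while keeping runs reproducible on a laptop:
default bulk cohorts of 400 genes × 200 samples with four 50-gene modules
(the module-recovery condition), 250-gene cohorts for the end-to-end
nomination runs, 400-gene / 24-module cohorts for neighborhood validation
(many small modules keep a hub's 2-layer neighborhood well under the 10%
cap, the regime the validation is meant for), 200 genes × 500 samples for
null survival calibration, and 300-cell single-cell matrices.  Monte-Carlo
defaults: 100 hub permutations in the API default, raised to 1000 in the
worked analyses so that empirical hub p-values resolve well below 0.05
(the asymptotic p of a planted hub in an m-gene module is ≈ 1/m; finite
permutation counts add binomial noise around it); 500 MDC permutations
(the two-sided floor 2/(n_perm+1) must clear the BH threshold); seeds fixed
and propagated through `numpy.random.SeedSequence`.

Degenerate inputs are contracts, not crashes: compactness rejects
disconnected or sub-3-vertex graphs; hub detection rejects n_perm < 19;
empty rankings and empty enrichments return degenerate results (k = 0,
p = 1) rather than raising; all-censored cohorts and rank-deficient designs
raise informative errors (the latter naming the collinear columns).

## Known limitations

* The modularity optimizer is a greedy multilevel heuristic; it optimizes Q
  approximately, as exact maximization is infeasible.  Different igraph
  versions could in principle return different partitions at fixed seed.
* The MDC statistic is one reasonable formalization of "module differential
  connectivity" (mean intramodule |r| connectivity ratio with a
  label-permutation null); other definitions exist.
* Covariate residualization is a single joint linear pass over batch and
  demographic covariates; a two-stage batch-then-demographics scheme would
  give slightly different residuals.
* The cis/trans window is symmetric around the TSS and ignores strand
  direction beyond the TSS position itself.
* Quantile normalization assumes comparable global distributions across
  samples; it is applied cohort-wide, not per batch.
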
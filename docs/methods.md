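# Methods

This note documents the models, numerical choices, and limitations of
`stressnet`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, and
what the synthetic-data tests do and do not demonstrate.

## Model

Gene expression for condition k is modelled as multivariate normal with
precision matrix Θ_k; a nonzero off-diagonal entry θ_ij^k means genes i
and j are conditionally dependent given all others, i.e. connected in
the condition-k co-expression network.  Edge strength is reported as the
partial correlation r_ij = −θ_ij/√(θ_ii θ_jj), and an edge enters the
network only if |r_ij| ≥ τ (default τ = 0.05).  Because p typically
exceeds n, estimation is penalized:

- an L1 penalty λ1 on off-diagonal entries induces sparsity
  (diagonals are never penalized — this keeps positive definiteness
  attainable and matches standard graphical-lasso practice);
- a sequential fused penalty λ2 shrinks differences between
  *neighbouring* conditions in a chain, borrowing strength across
  conditions without the quadratic blow-up of all-pairs fusion;
- binary condition-adaptive weights W^{k,k+1} switch fusion off for gene
  pairs whose association genuinely differs between the two conditions.

### Condition chain

The chain is the leaf order of average-linkage hierarchical clustering
on Euclidean distances between per-condition mean expression profiles.
Conditions are name-sorted before clustering so ties and reflections
resolve deterministically; two identical conditions are guaranteed
adjacent (their distance is zero, so they merge first).

### Screening weights

For each consecutive condition pair and each gene pair, the Fisher
statistic z = (atanh r_k − atanh r_{k+1}) / √(1/(n_k−3) + 1/(n_{k+1}−3))
is computed from the per-condition correlations (values clamped to
±(1−10⁻¹²) before atanh).  Two-sided p-values are Benjamini-Hochberg
adjusted across all gene pairs of that condition pair and fusion is
disabled where q < α (α = 0.05).  This is one defensible instantiation
of condition-adaptive weighting; the screening statistic is not uniquely
determined by the analysis the package reproduces, and alternatives
(e.g. likelihood-ratio screens) would slot in behind the same
`FusionWeights` interface.

### Objective scale and sample sizes

The fitted objective weighs every condition's loss equally,

    Σ_k [tr(S_k Θ_k) − log det Θ_k] + penalties,

with S_k on the correlation scale.  Sample sizes enter (i) the screening
statistics and (ii) model selection, via

    AIC = Σ_k [n_k tr(S_k Θ_k) − n_k log det Θ_k + 2 E_k],

E_k = number of nonzero upper-triangle off-diagonal entries
(|θ| > 10⁻¹⁰).  Keeping the fitting objective unweighted makes the
λ grid {0.01, 0.03, 0.05} meaningful on the correlation-likelihood scale
and makes λ2 = 0 decouple *exactly* into independent single-condition
graphical lassos at the same λ1 — a property the test suite exercises.
An n_k-weighted likelihood would require rescaling the grid per dataset.
Ties in the grid search break toward smaller λ1, then smaller λ2.

### ADMM

Consensus splitting with fixed step ρ = 1.0 (no adaptive scaling, so
runs are bit-for-bit reproducible):

- Θ-update: per condition, an eigendecomposition problem with the
  closed-form spectral solution; always positive definite.
- Z-update: elementwise along each gene pair's chain of K values —
  first the fused-lasso prox (total variation along the chain, strength
  λ2/ρ on fused links), then soft-thresholding at λ1/ρ.  Gene pairs are
  grouped by their binary weight pattern; within a pattern the chain
  splits into maximal fused runs.  Runs of length two have a closed
  form; longer runs are solved by FISTA on the box-constrained dual of
  the TV prox (vectorized across all gene pairs in the group, iterated
  to a 10⁻¹² step tolerance — exact for practical purposes).  This
  replaces a per-pair dynamic program with a fully vectorized solve.
- Convergence: relative primal and dual residual norms below
  `admm_tol` (default 10⁻³, default `max_iter` 100).  The returned
  estimate is the symmetrized consensus variable Z, which is exactly
  sparse; when the run converged it is checked positive definite (a
  violation raises, since it indicates a solver bug).  Non-convergent
  fits are flagged, kept in the AIC table, and remain eligible for
  selection — they are reported, not discarded.

`glasso_single` is the K = 1 specialization of the same solver and
doubles as the decoupling reference; tests additionally compare it to an
independent projected-gradient solver on the graphical-lasso dual and to
scikit-learn's coordinate-descent implementation.

## Preprocessing

- **CPM filter**: a gene is removed when its CPM is below 10 in at least
  ⌈0.30·S⌉ of the S samples.  The ceiling convention pins the boundary:
  with S = 10, three low samples remove the gene, two keep it.
- **GO-BP filter**: genes without a biological-process annotation are
  excluded (the network gene universe equals the enrichment background).
- **log2(CPM + 0.5)**: the 0.5 pseudo-count is a package default; any
  positive prior is accepted.
- **Smoothed quantile normalization** (group factor = condition): each
  sample's sorted values are replaced by w·(overall mean quantile
  profile) + (1−w)·(group mean profile), with per-quantile weight
  w = SSW/(SSB+SSW) computed across the samples' quantile profiles and
  smoothed by a running median spanning 5% of the quantiles (window size
  is a package choice).  Quantiles where groups genuinely differ (large
  between-group sum of squares) keep their group profile; the rest are
  driven to the common reference.  Ties within a sample receive averaged
  reference values; rank order is restored per sample.
- **Empirical-Bayes adjustment**: per gene, a linear model on retained
  plus unwanted covariates (dummy-coded, centered); unwanted
  coefficients are shrunk toward their across-gene mean with weight
  τ²/(τ² + s²_g) (between-gene variance over between + per-gene sampling
  variance), and only the unwanted fitted component is subtracted.
  Noise-free batch offsets are removed to machine precision; retained
  contrasts are untouched by construction because the centered designs
  are fitted jointly.  Note that removing real batch variance shrinks
  every gene's total variance, so R²-type measures of retained signal
  rise slightly after adjustment; the package's calibration checks
  therefore bound the *aggregate* change of treatment R² (≤10%) while
  requiring per-gene batch R² to fall below 0.05.
- **Standardization**: zero-variance genes are dropped (and reported —
  they cannot enter a correlation-scale GGM), remaining rows centered
  and scaled to unit *population* (1/n) variance.  Scaling to unit
  variance goes slightly beyond plain mean-centering; it is deliberate,
  since the solver consumes correlation matrices.
- Mean–variance precision weights (voom-style) are *not* computed: the
  solver consumes the unweighted log-scale matrix.

## Synthetic data

`make_precision_set` places ±magnitude entries at sampled off-diagonal
positions (a shared backbone present in all conditions plus private
positions per condition) on a unit diagonal, then repairs to diagonal
dominance — when the minimum eigenvalue is below 0.1, |min eig| + 0.1 is
added to the diagonal.  This is standard GGM simulation practice; note
the repair scales down realized partial correlations (an entry of 0.3
over a repaired diagonal of ~1.4 yields |r| ≈ 0.21).

`simulate_expression` draws latent z ~ MVN(0, Θ_k⁻¹) per sample, maps it
through softplus(z + gene baseline + batch offset) to positive means,
scales to a library size drawn uniformly from the configured range, and
draws negative-binomial (gamma-Poisson) counts with dispersion 0.1 —
overdispersed like RNA-seq, which the preprocessing must survive.
Counts are then rescaled (multiply and round) so each column hits its
sampled library size: this makes the library-size contract exact at the
cost of a slight distortion of the count distribution.  Batches cycle
within each condition, so batch is never confounded with treatment.
What the generator does *not* emulate: realistic library-size or GC-bias
distributions, gene-length effects, count correlations induced by
shared technical factors, or read-level artifacts.  Passing tests
demonstrate correctness of the pipeline's logic and its statistical
calibration under the stated generative model, not performance on any
real compendium.

`make_species_panel` plants HOG-level edges: a chosen fraction receives
species support covering all three clades required by the conservation
rule, every other edge receives support that provably misses at least
one required clade, so a correct classifier recovers the planted set
exactly.  Each HOG owns several genes per species so the projection's
many-to-one collapse is exercised.

## Cross-species comparison

Gene edges project to HOG pairs; edges with an unmapped endpoint are
dropped and counted, as are within-HOG (paralog-paralog) edges, which
carry no cross-species signal.  Edges are unordered and sign-agnostic:
conservation requires presence of the association, not equality of the
partial-correlation sign.  The conservation rule looks only at the
species set of an edge's provenance (conditions are aggregated, matching
the union-network setting in which the rule is applied).  Classification
runs on the provenance-merged union of the per-species HOG networks;
`intersect_across_species` serves the separate pairwise-comparison
use-case.  Connected components follow the standard definition, with
isolated nodes counting as singletons; hub ties break lexicographically
by gene id.

## Enrichment

p = P[X ≥ k] under Hypergeom(N, K, n) with term sizes K computed on the
background-projected annotation; BH (not the slightly different
q-value-package estimator) across tested terms, filtered at p ≤ 0.05 and
q ≤ 0.05, term sizes restricted to [10, 500].  No GO-DAG ancestor
propagation is performed — terms are used exactly as annotated; that is
a documented limitation for annotations that only label leaves.

## Pipeline and reproducibility

`run_all` chains the six stages on a flat sectioned config (unknown keys
rejected; the snapshot is written next to the outputs).  All randomness
derives from one global seed, hashed per stage name into sub-seeds below
2³¹, so stages are individually reproducible and two runs with the same
config produce byte-identical TSVs.  A failing stage aborts the run,
names itself in the raised error, and leaves a `.partial` marker.

Default problem sizes (30 genes, 3 conditions, 120–200 samples per
condition, 9-species panels with ~40 HOG edges) keep the full synthetic
study — including the 3×3 penalty grid — in the seconds range; all
statistical floors quoted in the tests (e.g. shared-edge recall and
precision ≥ 0.7) were fixed once against an oracle run at exactly these
conditions and then frozen as regression checks.

## Known limitations

- Pairwise (non-sequential) fusion is supported only where it coincides
  with the sequential chain (K = 2, or λ2 = 0).
- The screening rule is one of several defensible condition-adaptive
  weight constructions.
- AIC uses the raw nonzero count as degrees of freedom; no
  finite-sample correction.
- No cross-validated penalty selection, no GPU path, no gene-tree-aware
  orthology refinement, no visualization layer.
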
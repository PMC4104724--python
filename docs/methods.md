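# Methods notes

## Model and procedure

The analysis treats a case/control expression study as a single
multivariate regression of the binary phenotype (0 = control, 1 = case)
on all probes at once, estimated by partial least squares. The stages run
in a fixed order: standardize → cross-validated choice of the number of
latent variables → NIPALS fit → VIP scoring → permutation FDR → gene
selection → hypergeometric enrichment → induced-subnetwork hub calling.
The cross-validated h is frozen before the permutation stage and reused
for every permuted refit; re-running CV inside each permutation would
change what the null distribution estimates.

### NIPALS conventions

* **Standardization.** Columns of X (probes) are mean-centered and, by
  default, scaled to unit variance (`scale_columns`); y is mean-centered.
  Without scaling, high-variance probes dominate the covariance weight
  `w = X^T u` and VIP mostly ranks variance, not association. Scaling is
  a switch because both conventions are defensible; all shipped defaults
  use it. Zero-variance probes are dropped with a logged list and appear
  in result tables with NaN scores.
* **Deflation** uses the standard form `X ← X − t(tᵀX)/(tᵀt)`,
  `y ← y − t(tᵀy)/(tᵀt)`. (The un-normalized form `X − ttᵀX` is only
  dimensionally consistent when ‖t‖ = 1; dividing by tᵀt is the same
  operation stated for unnormalized scores.)
* **Convergence** is `‖u − u_prev‖₂ < tol` with tol = 1e-8. For a
  univariate response the inner loop converges on the first pass — the
  first weight is exactly `Xᵀy/‖Xᵀy‖` — so initialization with u₀ = y is
  deterministic and nothing is gained by randomizing it. Iteration
  counts are recorded per component (`n_iter_`).
* **Sign convention.** Each weight vector is flipped so its
  largest-magnitude entry is positive. VIP uses squared weights and the
  predictions use matched products of flipped quantities, so this pins
  down reproducibility across platforms without changing any result.
* **Classification rule.** Continuous predictions are thresholded at
  0.5, the midpoint of the 0/1 coding; the threshold is a constructor
  parameter.
* Degenerate inputs raise typed errors: non-convergence names the
  component; a numerically zero score or weight raises a rank-deficiency
  error carrying the number of extractable components.

### VIP and the pooled permutation FDR

VIP weights each component's squared weight by the squared Pearson
correlation of the binary phenotype with that component's score; weights
are unit-norm, so `Σ_j VIP_j² = p` exactly — this identity is asserted in
tests after every fit, including inside permutation replicates.

The FDR estimator pools null VIPs across all probes and permutations and
divides the strict-exceedance count by `n_perm · p`. Two properties are
worth knowing:

* It is *not* the conventional exceedance-over-discoveries permutation
  FDR. The conventional estimator is available as
  `pooled_fdr(..., method="conventional")` for comparison; the pooled
  form is the default and is what the pipeline uses.
* With strict inequality and no "+1" correction it is marginally
  anti-conservative under the global null: on fully null 1000-probe
  63/20 cohorts the expected fraction of probes with FDR < 0.01 is
  ≈ 0.0104 rather than ≤ 0.01 (measured over 40 simulation seeds; the
  result is the same with cross-validated and with fixed h, so it is not
  a model-selection artifact). Under real signal the estimator is
  strongly conservative for null probes, because planted probes absorb
  most of the weight mass in the observed fit while permuted refits
  spread it uniformly.

Selection is strict (`fdr < threshold`, default 0.01), and direction is
the sign of (case mean − control mean) of the probe's log2 values.
A gene counts as differentially expressed when any of its probes is
selected. Permutations that fail to refit (rank exhaustion) are redrawn
with a logged count. The frame-level entry points put samples into a
canonical sorted-id order before computing anything, so jointly
reordering expression columns and phenotype rows cannot change any
result bit.

### Cross-validation

Folds are stratified by class, seeded, and dealt round-robin after a
per-class shuffle; a class smaller than the fold count is an error.
Each fold fits once at `h_max` and evaluates all smaller h by truncating
the component expansion (components are nested, so this is exact). Ties
in mean accuracy break toward the smallest h.

### Enrichment

The universe for each namespace is the annotated genes appearing in at
least one set of that namespace — pathway-mapped genes for pathway
tests, GO-annotated genes for GO tests — mirroring how array-wide
"mapped genes" are counted separately per database. p-values are
upper-tail hypergeometric (via `scipy.stats.hypergeom.sf`, stable in
log space); sets with zero overlap are untestable for over-representation
and suppressed. Both raw p and Benjamini–Hochberg q (per namespace) are
reported; thresholding is left to the caller. BH is this package's
choice of adjustment; nothing in the upstream convention forces it.

### Network hubs

Degrees are computed on the subnetwork induced by the selected genes,
not on the full background graph — the hub question asked here is "which
disease-associated proteins are highly connected *among themselves*".
The hub cutoff (default 10) is inclusive: a rule of "degree over 10"
read strictly would exclude a degree-10 node, but the reference hub list
this convention reproduces includes one, so ≥ is the default and strict
mode is a flag.

## Synthetic data: what it emulates and what it does not

The generator mirrors a two-group blood-microarray design: by default 63
cases and 20 controls; per-probe baseline log2 intensities uniform on
[4, 12] (the realistic dynamic range of RMA-normalized arrays); i.i.d.
Gaussian noise on the log2 scale with sd 1.0; planted DE probes shifted
by ±effect_size in cases with a 50/50 direction split (`up_fraction`
exposes asymmetric designs; odd counts give the extra probe to the up
side). Probe→gene annotation is many-to-one (1.2 probes per gene, 2%
unannotated) so the probe-collapse rule is exercised. Planted enriched
sets draw a fraction `enrichment_strength` of members from DE genes;
the interaction graph is Erdős–Rényi with hubs topped up to a guaranteed
degree.

Deliberately **not** modeled: probe-level effects within probe sets,
batch and array-specific technical artifacts, correlated gene modules,
heavy-tailed noise, and intensity-dependent variance. Passing tests
therefore demonstrate correctness of the algorithms and calibration
under the stated generative model — not robustness to real microarray
artifacts, which the upstream normalization is assumed to have handled.

## Problem sizes in tests and the acceptance script

Simulation-based checks run at 1000–2000 probes with 100–200
permutations and ≤ 20 seeds; these sizes give stable pass/fail behaviour
for the properties being checked (sensitivity ≈ 0.95 at effect 1.5;
null-calibration means within ±0.003 of their expectation) while keeping
the default suite fast. The permutation default in the pipeline itself
is 10 000; tests and the acceptance script override it explicitly.

## Known limitations

* Single binary response only; no multi-class or continuous phenotypes.
* The pooled FDR's slight null anti-conservatism (above) is inherent to
  the estimator's printed form; use `method="conventional"` if a
  conservative null is required.
* Gene-level aggregation is "any probe selected"; no gene-level VIP.
* GO annotations are used as given — no ontology-graph propagation.
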
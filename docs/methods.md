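# Methods

This note documents the models implemented in `neuromediate`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish about real data.

## The statistical chain

The package operationalizes one question: *to what extent is the association
between a polygenic score (PGS) and an intelligence score mediated by
regional brain properties?* The chain is:

```
phenotypes + connectomes
  → per-stream outlier exclusion (3·IQR rule)
  → group Holm-Bonferroni pruning of each connectome modality
  → shortest-path nodal/global efficiency per subject
  → hemisphere averaging into region tables
  → global mediation (one whole-brain metric at a time)
  → regularized regional mediation (all regions of a family at once)
  → P-FIT annotation of selected regions
```

## Power analysis

`required_sample_size` implements the fixed-model "R² deviation from zero"
F test: numerator df = number of predictors `p`, denominator df
`N − p − 1`, noncentrality `λ = f²·N`. The function scans N upward from the
minimal admissible size (`p + 2`) and returns the first N whose power
reaches the target; power is non-decreasing in N, and minimality is
asserted by evaluating N−1. The query records a "two-tailed" flag for
fidelity with common calculator inputs, but the F test itself is inherently
one-sided and α is used as given.

## Synthetic cohorts

The generator is a structural equation model with everything standardized
internally:

* Covariates: age ~ U(18, 75), balanced binary sex, four standard-normal
  ancestry components. These match a young-adult cohort only loosely by
  design; the analysis chain is covariate-agnostic.
* Two independent standard-normal PGS ("EA-like", "GI-like").
* Each designated mediator region `j` carries a latent
  `M_j = a_j·PGS + γᵀC + ε_j` with `Var(M_j) = 1`. For surface-area and
  thickness mediators the latent *is* the regional value (affinely
  rescaled to plausible units, ~mm² and ~mm). For connectome-efficiency
  mediators all edges incident to the region's two nodes are scaled by
  `1 + κ·M_j` (κ = 0.15, floored at 0.05), which makes the region's nodal
  efficiency an attenuated, monotone readout of the latent.
* Outcome: `Y = Σ b_j M_j + c′_EA·PGS_EA + c′_GI·PGS_GI + δᵀC + ε_Y`,
  reported as an IQ-like score `100 + 15·Y/sd(Y)`.

**Calibration.** When no explicit direct effects are supplied, each
`c′_k` is solved from the target incremental R² (`τ_k = √t_k`, so
`c′_k = √t_k − Σ_j a_j b_j`), and the outcome noise variance is computed
analytically from the full covariance of the primitives so that
`Var(Y) = 1`. Adding PGS_k to a covariate-only regression then raises R² by
exactly `τ_k²` in expectation (defaults 0.033 and 0.048). Configurations
whose paths leave no room for the outcome noise, or whose implied direct
effect is not a valid standardized path, are rejected with a message.

**Structural edge weights.** Streamline counts are heavily right-skewed, so
each edge has a lognormal template weight `exp(N(3, 1))` shared across
subjects, with subject-level multiplicative noise `exp(0.3·N(0,1))`. A
configured fraction (default 0.35) of edges is truly absent: their template
is zero and subject values are drawn as |N(0, 0.02)|, hovering near zero so
that pruning has genuine spurious connections to find. No empirical
streamline-count distribution was available to fit; the lognormal is a
stand-in, and any analysis conclusion that depends on the exact weight
distribution should be re-checked against real matrices.

**Functional data.** Node-level time courses (default 208 samples) follow a
low-rank factor model: each region loads 0.55 on one of 12 "network"
factors and 0.25 on a global factor; 8 shared nuisance signals (motion-like,
white-matter-like, ventricle-like) load on all nodes and are returned
separately so the connectivity step can regress them out; white noise has
unit SD. One cortical region (by default the last, both hemispheres) loads
on nothing — after pruning its two nodes are isolated and removed, so the
functional family has 179 candidate regions under the full 180-per-hemisphere
parcellation, reproducing the node-removal behaviour of group pruning.
The defaults give no PGS effect on functional connectivity.

**Parcellation.** 180 cortical + 8 subcortical regions per hemisphere →
376 structural nodes and 188 hemisphere-averaged structural regions; the
functional network uses the 360 cortical nodes. All counts are configurable;
the generator's naming is generic (`A001…`, `SC1…`).

**Outlier injection.** Optionally, k subjects receive extreme values cycling
through the three analysis streams (anatomical: ×1.5 surface area;
structural/functional: ×2 all weights), and their ids are recorded in the
ground truth so exclusion can be tested.

## Group pruning

Per iteration: (1) pooled SD over *all* currently retained upper-triangle
weights of all subjects; (2) per retained edge, a one-tailed z statistic
`mean/(pooledSD/√S)` against the null weight 0; (3) Holm step-down at α
(default .01) over the retained edges; (4) edges failing the step-down are
removed; iterate until no removal, then drop zero-degree nodes once. The
pooled-variance z form follows the method's published description, which is
not algorithmically explicit; a conventional per-edge one-sample t variant
is available via `PruneConfig(statistic="t")`. A `max_iterations` cap
(default 1000) guards against oscillation, with convergence logging.

Because the test is one-tailed *greater*, edges with negative mean Fisher-z
weights are pruned, so retained functional edges have positive group means —
but a single subject may still carry a negative weight at a retained edge.
Distance computations therefore reject negative weights by default and offer
`clip_negative=True` (used by the pipeline for functional networks), which
treats such subject-level values as absent edges.

## Distances and efficiency

Edge length is `1/weight` for both modalities (strong connections are
short); shortest paths are computed with Dijkstra's algorithm; disconnected
pairs have infinite distance and contribute `1/∞ = 0`. Nodal efficiency is
the mean inverse distance to all other nodes; global efficiency is exactly
the arithmetic mean of the nodal efficiencies. Tests verify the Dijkstra
result against a brute-force Floyd–Warshall triple loop, the identity
`E = mean(E_i)`, linear scale equivariance `E(sW) = s·E(W)`, and the
monotonicity of efficiency under edge removal.

## Outliers, correlations, incremental R²

A value is an outlier when it deviates more than three interquartile ranges
from the variable's *mean*. Quartiles use linear interpolation between order
statistics (the numpy default); the rule is affine-equivariant. Exclusion is
per analysis stream (anatomical / structural / functional), so the streams
retain different n. Partial correlation is the Pearson correlation of
covariate-residualized vectors with covariate-adjusted df; which covariates
enter (age and sex only, or also the ancestry components) is the caller's
choice. Incremental R² is the difference of nested-OLS R² values and equals
the squared semi-partial correlation.

## Mediation

**Single mediator.** `a` from `m ~ x + C`; `b`, `c′` from `y ~ m + x + C`;
total effect from `y ~ x + C`. For complete-case OLS these satisfy
`total = c′ + a·b` to numerical precision. Uncertainty: Sobel
(delta-method) SE for `a·b`, optional HC3-robust regression SEs, optional
seeded percentile bootstrap for the indirect effect. This is a deliberate
deviation from fitting the just-identified path model in an SEM framework
with a robust ML estimator: the point estimates coincide; only the
uncertainty quantification differs.

**Regularized multi-mediator.** All inputs must be standardized and
residualized for covariates (checked). Penalties use the glmnet
parameterization `(1/2n)RSS + λ(α|β|₁ + (1−α)|β|₂²/2)` with mixing
α = 0.5 by default (the elastic net's mixing weight is a free choice here;
it is configurable). Path b regresses the outcome on all p mediators with
the exposure included *unpenalized* — implemented exactly by profiling the
exposure coefficient out of the objective (residualize y and M on x, run
the penalized fit, recover the x coefficient by OLS on what the fit leaves
unexplained). Path a is a multi-response regression of the mediator matrix
on the exposure with one shared penalty; with a single predictor the
per-mediator solution is a closed-form soft threshold, and the shared λ is
chosen on a glmnet-style geometric grid (100 values, ratio 1e−3). A
reversed formulation (exposure regressed on all mediators) is available via
`path_a_direction="x_on_mediators"`; the refit makes the final effect sizes
insensitive to this choice. Both penalties are selected at the minimum
cross-validated MSE over k = 80 folds (fold assignment seeded); the
one-standard-error rule is not used. Selection: penalized `|a_j·b_j| >
0.001`; path-level non-zero sets use `|a_j|` or `|b_j| > 0.01`. The
selected set is refit without penalty (per-mediator `m_j ~ x` for a_j;
joint `y ~ M_sel + x` for b_j and the shared c′) — the debiased effects.
Degenerate cases (empty selection, more selections than `n − 2`,
zero-variance mediators, `k > n`) raise informative errors.

## P-FIT membership

`overlap_fractions` counts, for each area of the fine parcellation, the
fraction of its grid elements carrying each label of the coarse
(Brodmann-style) map; the denominator is the area's full element count, so
rows sum to ≤ 1 when elements are unlabeled in the coarse map. An area is
P-FIT when its best overlap with any P-FIT Brodmann area reaches the 0.8
threshold in *both* hemispheres (ties at exactly 0.8 count), or when it is
flagged by the meta-analysis list in both hemispheres. Real annotation
volumes are not shipped; `synthetic_label_maps` builds a labelled-synthetic
pair with known overlaps for testing and for annotating simulated runs.

## Problem sizes and numerical choices

* The generator calibration checks run at n = 10,000 (phenotypes only) over
  20 seeds; the regularized-mediation recovery benchmark at n = 1000,
  p = 100, 20 seeds, k = 80 folds.
* The end-to-end recovery property (10 seeds) uses a reduced 68-node
  parcellation (30 cortical + 4 subcortical per hemisphere) with 10 CV
  folds, which preserves every pipeline stage while keeping the property
  test fast; the single full-scale smoke run uses the complete 376-node
  parcellation at n = 600 with the default k = 80.
* Group connectome stacks are stored as float32 (a 600×376×376 stack is
  ~340 MB); all test statistics are computed in float64.
* CV folds come from a seeded shuffled k-fold split; the pipeline's master
  seed fans out to the generator seed and the CV seed, both recorded in the
  report.

## Known limitations

* The synthetic cohort has linear, homoscedastic, Gaussian path structure;
  real effect sizes, distributional shape, site effects, and
  motion-connectivity confounding are not emulated. Passing recovery tests
  show the chain is consistent and unbiased *under its own assumptions*,
  not that it would recover mediators at these rates in a real sample.
* Nodal efficiency is an attenuated readout of the planted latent for
  efficiency mediators, so efficiency-family recovery is weaker than
  anatomical-family recovery at equal path strength — visible in the
  reduced-scale example output.
* The pooled-variance pruning statistic treats the network-wide weight
  dispersion as the per-edge null scale; with heavy-tailed structural
  weights this removes genuinely weak edges along with spurious ones. This
  is inherent to the method, not a defect of the implementation.
* The elastic-net penalty sequence follows the solver's default geometric
  grid; a differently tuned sequence can change which borderline candidates
  clear the selection threshold, though not the refit estimates of clearly
  selected ones.
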
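# Methods

## Data model

The core object is an order-3 temporal tensor: for each sample `i` a set of
pseudotime points `T_i ⊂ [0, 1]` and, at each point, a vector of expression
values over a shared gene panel.  Grids are sample-specific and irregular —
after trajectory binning, bins with no cells are simply absent — and nothing
is ever imputed at unobserved (sample, time) pairs; every model fit,
residual, and diagnostic sums only over observed entries.

Pseudotime is an input, assumed comparable across samples (cells from all
samples ordered on one common trajectory).  Internally all pseudotimes are
rescaled affinely to [0, 1] using the training data's global minimum and
maximum; the map is stored so held-out data pass through the *training* map
(clipping to [0, 1] outside the training range).  The [0, 1] domain is a
package convention: the Bernoulli-polynomial kernel pieces are natural on
the unit interval and the unit-integral constraint on temporal loadings
needs a fixed domain.  Before binning, duplicate pseudotimes within a sample
are legitimate (two cells can share a value) and are kept as separate
observations unless time *and* expression vector are byte-identical.

## Preprocessing

1. **Binning** (default 50 equal-width bins, left-closed/right-open, last
   bin closed): each nonempty (sample, bin) pair becomes one metacell whose
   value is the per-gene *median* of the cells in the bin (even counts:
   mean of the central pair) placed at the bin midpoint.  Fifty bins match
   the resolution commonly used for trajectories of this kind; with
   sparsely sampled trajectories fewer bins give more cells per metacell.
2. **Prevalence filter**: keep genes with value strictly greater than 0.1
   in at least 5% (inclusive) of metacells.  Both thresholds configurable.
3. **HVG selection**: per gene, mean and standard deviation (divisor N−1)
   across all metacells; a LOESS fit of sd on mean (tricube-weighted local
   polynomial regression, span 0.75, degree 2 — the conventional defaults
   of the loess family, both configurable); genes with strictly positive
   residual are retained.  Both the filter and the HVG statistics are
   computed on *binned* metacells, i.e. after step 1.
4. **Standardization**: per gene, zero mean and unit variance (divisor N−1)
   pooled over all metacells.  Constant genes are dropped with a logged
   warning.  The fitted means/sds can be frozen and applied to held-out
   data, which the cross-validation benchmark uses to avoid leakage.

## Kernel and smoothness penalty

Temporal loadings live in the RKHS of the rescaled Bernoulli polynomial
kernel on [0, 1],

    K(s, t) = 1 + k1(s)k1(t) + k2(s)k2(t) − k4(|s − t|),
    k1(s) = s − 1/2,  k2 = (k1² − 1/12)/2,  k4 = (k1⁴ − k1²/2 + 7/240)/24,

(k_r = B_r/r!, the scaled Bernoulli polynomials; e.g. K(1/2, 1/2) = 321/320).
The squared norm used for diagnostics is

    ‖ξ‖²_H = ∫(ξ″)² dt + (∫ξ dt)² + (∫ξ·k1 dt)² + (∫ξ·k2 dt)²,

i.e. curvature energy plus the squared projections on the polynomial basis
{1, k1, k2}.  Numerically: integrals by composite Simpson quadrature on a
uniform grid (default 101 points; Simpson rather than trapezoid so that the
polynomial projections of low-order functions are exact), second derivative
by central finite differences with second-order one-sided stencils at the
endpoints.

A caveat worth knowing: this explicit norm and the kernel above are only
*approximately* dual.  The kernel is exactly reproducing for the classical
norm whose linear term is (∫ξ′ dt)²; with the k1-projection variant used
here the identity ‖K(·, u)‖²_H = K(u, u) holds to 0.01% at u = 1/2 but
deviates by ~6% at u = 1/4 (verified symbolically, not a quadrature
artifact).  The penalized fits themselves always use the kernel-native
quadratic form c'Gc of the representer expansion, which is internally
consistent; the explicit norm is a diagnostic.

**Penalty weight `C_K`** (PenaltyConfig): default `1e-4 ×` the number of
observed tensor entries in the fit.  The data term grows with the number of
observations while the penalty does not, so per-observation scaling keeps
the effective smoothing comparable across dataset sizes; an absolute weight
is available (`scale_by_observations=False`).  The constant was calibrated
on synthetic data: at `1e-3` the smoother visibly biases moderately sharp
trends (a logistic temporal factor under noise is recovered with temporal
cosine ~0.90), while at `1e-4` recovery is ≥ 0.98 and fits on noisy data
still have markedly lower curvature energy than unpenalized ones.

**Smoother**: minimizing `Σ_u w_u (z_u − ξ(t_u))² + C ‖ξ‖²_H` over the RKHS
reduces, by the representer theorem, to `(W G + C I) c = W z` on the
distinct observed times.  Duplicate times are collapsed exactly (summed
weights, weight-averaged targets); zero-weight points are dropped; singular
systems raise with the condition number.

## Decomposition algorithm

Components are fitted one at a time; after each fit the rank-1 term is
subtracted at every observed entry and the next component is fitted to the
residual.  Each component minimizes

    Σ (y_ijt − λ a_i b_j ξ(t))² + C_K ‖ξ‖²_H,   ‖a‖ = ‖b‖ = 1, ∫ξ² = 1,

by alternating three exact subproblem solves:

- **(B) temporal update** — for fixed (λ, a, b) the objective separates
  over time points with weights `w = (λ a_i)²` and collapsed targets
  `z = Σ_j y_ijt b_j / (λ a_i)`; the smoother above gives the exact
  unconstrained minimizer, which is then renormalized to ∫ξ² = 1
  (quadrature) with the scale carried by λ.
- **(A) sample/gene update** — for fixed ξ, collapsing the tensor against ξ
  per sample (`X[i, j] = Σ_t y_ijt ξ(t) / Σ_t ξ(t)²`) turns the joint
  (λ·a, b) update into a row-weighted rank-1 approximation with weights
  `w_i = Σ_t ξ(t)²`; the exact solution is the leading singular pair of
  `diag(√w) X`.  The weighting matters on irregular grids: the plain SVD of
  X is not the minimizer and can increase the objective.
- **(C) scale** — λ is the closed-form least-squares scale (equal, by
  construction, to the norm of the weighted-SVD scale vector).

Each cycle ends with (A)+(C), which makes the exported triple exactly
self-consistent: the per-sample least-squares scale against (b, ξ) equals
λ·a_i identically, the property out-of-sample projection relies on.

**Convergence and monotonicity.**  Because the unit-norm constraint on ξ is
enforced by renormalization *between* exact subproblem solves, the raw
objective is not a Lyapunov function of the iteration — near a fixed point
it fluctuates at convergence scale.  The iteration therefore tracks the
incumbent (lowest objective seen), stops when the absolute objective change
falls below `rel_tol` (default 1e-5) or after `max_iter` (default 100)
cycles, and returns the incumbent; `objective_trace` records the incumbent
improvements and is non-increasing by construction.

**Initialization.**  Spectral (default, deterministic): the collapse-and-SVD
start is evaluated for three orthonormal polynomial shapes of pseudotime
(constant, linear, quadratic shifted-Legendre) and the shape with the
largest leading weighted singular value wins — a constant-only start is
blind to components whose temporal factor integrates to zero.  Random:
a, b drawn uniformly from the unit sphere (seeded).  On the default
simulation both starts recover the same component set; components with
near-tied scales may swap deflation order, which is inherent to sequential
CP fitting, so robustness comparisons should match components one-to-one
before comparing loadings.

**Sign convention** (CP factors are sign-ambiguous in pairs): flip (ξ, b)
so ∫ξ ≥ 0 — if |∫ξ| < 1e-8, so that the largest-magnitude extremum of ξ is
positive — then flip a so λ ≥ 0.

**Degenerate inputs**: an all-zero tensor (or residual) yields λ = 0 with a
`degenerate` flag; such components are skipped in deflation, reconstruction
and projection.

**Diagnostics**: `rss_trace` holds the residual sum of squares after each
deflation; per-component explained variance is the normalized RSS drop and
the cumulative value is `1 − rss_r / total_ss`.  Rank selection is left to
the user: start small and increase while components remain interpretable,
monitoring explained variance.

## Out-of-sample projection

Held-out samples (same gene panel, pseudotimes mapped through the training
rescale map) are embedded by holding the trained (b, ξ) of each component
fixed and computing the per-sample least-squares scale

    â_i = Σ_{j,t} y_ijt b_j ξ(t) / Σ_{j,t} (b_j ξ(t))²,

with the same sequential deflation as training.  Columns carry the product
scale λ·a and are deliberately not renormalized; downstream classifiers
standardize features, so only relative ordering matters.

## Gene embedding, modules, overlap

The gene embedding matrix stacks `B⁽ˡ⁾ = λ⁽ˡ⁾ b⁽ˡ⁾` columnwise.  Modules:
average-linkage hierarchical clustering of embedding rows under the
Pearson-correlation distance (1 − r), tree cut to k clusters, labels
renumbered by decreasing size (ties by first member).  k is user-chosen
(default: the fit's rank) and the linkage is exported so trees can be
re-cut.  Rows constant across components have undefined correlation and
receive sentinel label 0.  Metagenes are unweighted means of member-gene
values per (sample, time), computed on the standardized tensor.  The top-L
overlap proportion between two fits is `|A ∩ B| / L` for the top-L sets of
the |loading|-ranked gene lists (ties broken lexicographically for
determinism).

## Simulator and benchmark

The generator emulates a data-driven cohort simulation: 25 genes with three
pseudotemporal trend shapes — increasing logistic `1/(1+e^{−10(t−0.5)})`,
its mirror, and a Gaussian peak `exp(−(t−0.5)²/(2·0.15²))` — as parametric
stand-ins for GAM fits to real trajectory genes (a `curves` hook accepts
user-fitted functions).  Defaults: 161 samples randomly split into three
groups, 300 cells per sample with iid Uniform(0, 1) pseudotimes, additive
Gaussian noise sd 0.1 (raised to 3 when stressing phenotype prediction).
Group structure is induced by permuting, within each affected sample, the
values of the decreasing genes (group 2) and the peak genes (groups 2 and
3): permutation destroys the temporal trend while preserving every
per-sample marginal, so pseudobulk summaries are provably blind to it.

Three permutation nulls break the sample/trajectory linkage: per-gene
expression permuted across all cells; pseudotimes permuted across all cells
(membership kept); pseudotimes permuted within each sample.  All three are
measure-preserving permutations, and the two pseudotime schemes leave
per-sample gene means — hence Pseudobulk-PCA — exactly unchanged.

What the simulator does *not* emulate: count-level noise (values are
Gaussian around smooth curves, not log-transformed counts), gene-gene
correlation beyond the shared trends, varying cells per sample, batch
structure, or pseudotime estimation error (times are exact).  Passing
benchmarks therefore demonstrate the machinery's behaviour under the
stated generative model, not performance on real data.

The benchmark runs stratified K-fold cross-validation at the sample level:
per fold, the full pipeline (pseudotime rescaling, binning, standardization,
decomposition) is fitted on training samples only and test samples are
embedded by projection — the decomposition is refit per fold, the
conservative choice against leakage.  Classifiers: logistic regression
(default) or a 500-tree random forest, on training-fold-standardized
loadings.  AUC: rank-statistic for two classes, Hand–Till pairwise average
(one-vs-one macro) for three or more; reported per fold, as the fold mean,
and pooled over out-of-fold predictions.  The Pseudobulk-PCA baseline
averages cells per sample, z-scores genes across training samples (divisor
N−1, constant genes dropped), fits PCA on the training folds and transforms
test folds; the deterministic sign convention makes each component's
largest-magnitude gene loading positive.  Group-difference tests on single
loading vectors use the two-sided Wilcoxon rank-sum test (normal
approximation with tie correction, no continuity correction so identical
groups give p = 1).

Test-suite problem sizes are desk-scale by design: recovery tests use
20 × 15 tensors on 30-point grids; the benchmark contract uses 60 samples ×
100 cells over 5 simulation seeds with 5-fold CV; the initialization and
projection checks use the full 161-sample reference simulation.

## Known limitations

- Gaussian least-squares likelihood only; no count-distribution variants,
  no Tucker structure, no simultaneous rank-r fitting.
- No automatic rank or penalty selection; explained-variance diagnostics
  only.
- Single linear trajectory per fit; tree-structured pseudotime is out of
  scope (fit branches separately or concatenate).
- Pseudotime misalignment across samples violates the model's central
  assumption and will distort components.
- The explicit RKHS-norm formula is approximately dual to the kernel (see
  above); diagnostics relying on exact duality away from the domain center
  inherit that approximation.
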
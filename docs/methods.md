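# Methods

## Model and assumptions

Four models of adaptive trait evolution are implemented. The response
trait y follows an Ornstein–Uhlenbeck process with constant force α_y > 0
and rate σ_y, whose optimum θ_t is a deterministic function of a covariate
trait x: θ = β₁ + β₂x (linear; models OUBM, OUOU) or θ = β₁ + β₂e^{β₃x}
(exponential; models OUGBM, OUGOU), with the covariate itself evolving by
Brownian motion (σ_x) or an OU process (α_x, θ_x, σ_x). Assumptions:

- the tree is rooted, binary, with strictly positive branch lengths, and
  is rescaled so the maximum root-to-tip depth is 1; all rates are per
  unit of scaled tree height. Non-unit trees are rescaled with a warning.
- tips are treated as contemporaneous (the models target ultrametric
  trees); non-ultrametric input is accepted but the statistics' BM
  calibration then degrades.
- the optimum carries no noise of its own: it inherits all randomness
  from the covariate path, so inheriting (x, y) at internal nodes induces
  the correct optimum inheritance. The root optimum value is reported but
  never simulated. Root states default to (ρ_y, ρ_x) = (0, 0).

Integrating the response SDE over a branch of length t gives

    y_t = e^{−α_y t} y_0 + A_t + N(0, σ_y²(1 − e^{−2α_y t})/(2α_y)),
    A_t = β₁(1 − e^{−α_y t}) + β₂ α_y e^{−α_y t} ∫₀ᵗ e^{α_y s} g(x_s) ds,

with g(x) = x or e^{β₃x}. For the exponential optima the integral is the
time integral of a geometric Brownian/OU process and has no closed form
(only a known inverse-gamma limit law at long times for the mean-reverting
form, which we use as a distributional test).

A note on the exponential-OU optimum: applying Itô's lemma to z = e^{β₃x}
for an OU covariate gives log z_t = β₃[θ_x + e^{−α_x t}(x_0 − θ_x)] +
β₃σ_x e^{−α_x t}∫e^{α_x s}dW_s — i.e. the optimum is θ = β₁ + β₂e^{β₃x_t}
with x_t the exact OU solution, and the mean-reversion rate of log z is
α_x (not α_x β₃). The implementation uses this derived form throughout and
validates it against a brute-force Euler–Maruyama co-simulation of the
coupled SDEs. Likewise, the OUBM A-term variance implemented is the Itô
isometry result β₂²σ_x²[t − 2(1−e^{−α_y t})/α_y + (1−e^{−2α_y t})/(2α_y)]
(growing like t, as it must when the optimum tracks a random walk), and
the OUOU A-term variance includes the cross-covariance term
−2(1−e^{−(α_x+α_y)t})/(α_x+α_y) between the two stochastic integrals
driven by the same Wiener process.

## Simulation engine

One path-based engine serves all four models so that the branch-end
covariate and the optimum integral are automatically correlated. Per
branch of length t: an exact covariate path is sampled on a uniform grid
(100 Simpson intervals per unit branch length, minimum 10, rounded to
even; BM by cumulative Gaussian increments, OU by its exact transition),
A_t is evaluated by composite Simpson quadrature on that path, and y is
advanced with the exact Gaussian response transition. The β₁ part of A_t
is handled analytically. Noise per edge comes from a generator keyed by
(seed, edge id); replicates occupy rows of the same array, so results are
reproducible and vectorized across whole reference tables (one branch of
20 000 replicates costs one (20 000 × m) Gaussian draw).

Closed-form Gaussian expressions for the linear models serve as test
oracles only, never as the sampling path. Quadrature accuracy: doubling
the grid changes unit-branch integrals by < 1e−4; deterministic
integrands are reproduced to ~1e−9.

Degenerate inputs: σ = 0 is admitted as the deterministic limit; β₃ = 0
collapses the exponential models to a constant optimum β₁ + β₂ (used as a
model-reduction test against OUBM); the OUOU term with α_y = α_x uses the
analytic limit; (1 − e^{−2αt})/(2α) switches to its α → 0 limit t below
αt = 1e−12.

## Trees

Balanced trees use Grafen node heights (clade tip count − 1)/(n − 1),
rescaled to height 1, for n a power of two. Birth–death trees (defaults:
birth 2, death 0.5 per unit time, nominal age 2, tip sampling probability
0.5) are grown with dendropy until ⌈n/ρ⌉ extant tips, extinct lineages
pruned, and exactly n tips retained uniformly at random — ρ-sampling
conditioned on the sampled count. Because every tree is rescaled to unit
height before simulation, only tree *shape* enters the models; the
nominal age is not separately conditioned on. Polytomies are rejected
where contrasts are needed rather than silently resolved.

## Summary statistics

Twelve statistics per trait, computed on both the response and covariate
and concatenated (24 total): mean, median, sd (n−1), skewness and raw
(non-excess) kurtosis as standardized central moments; the mean, sd,
skewness and kurtosis of Felsenstein's standardized independent
contrasts; Blomberg's K (observed MSE₀/MSE over its BM expectation
(tr C − n/1ᵀC⁻¹1)/(n−1), with the GLS mean and C⁻¹ quadratic form);
Pagel's λ by profile likelihood on [0, 1] (mean and variance profiled out
in closed form; a 101-point grid plus one local refinement, resolution
~1e−3, matching a 1001-point grid; the scalar API adds bounded Brent);
and the GLS phylogenetic mean. The twelfth statistic is not pinned down
by the published description (eleven are listed); the GLS mean — which
that description defines explicitly — completes the set, and the
composition is configurable. Degenerate cases (constant vectors) impute
skewness/kurtosis/K as 0 with a warning so ABC distances stay finite.
Since the tree is fixed within a reference table, the contrast operator
is precomputed as an (n−1)×n matrix and the λ profile uses one symmetric
eigendecomposition of C, making whole-table statistics a handful of
matrix products. K, λ and the contrasts are cross-checked against R's
phytools/ape in the test suite.

## ABC

Rejection sampling: draw parameters from independent priors (default
broad uniforms: α_y ~ U(0,1), α_x ~ U(0,0.25), θ_x ~ U(−5,5),
σ_x ~ U(0,5), σ_y ~ U(0,2), β₁ ~ U(−1,1), β₂ ~ U(0,2), β₃ ~ U(−1,0); an
alternative elicited set with exponential forces, inverse-gamma rates and
a normal covariate optimum is provided), simulate, summarize, and accept
the ⌈total·δ⌉ rows with the smallest distances (ties by row index). δ is
an acceptance *proportion*, not an absolute threshold. The distance is
Euclidean with componentwise scaling by the median absolute deviation
across the reference table (mode `raw` gives the literal unscaled norm);
without scaling, variance-scale statistics dominate the norm. Posterior
model probabilities are accepted-label frequencies under a uniform model
prior (`rejection`) or multinomial-logistic class probabilities fitted on
the accepted rows (`mnlogistic`, used for cross-validation); Bayes
factors are their ratios. Pooling posterior samples across independent
runs (e.g. 4 × 5000 draws at δ = 0.01) mirrors the multi-run design of
the validation study.

Cross-validation draws a fresh birth–death tree per reference row (tree
variability is part of the prior predictive), holds out each validation
row in turn, and classifies it against all remaining rows.

## Scaled-down experiment sizes

The packaged experiments are desk-scale versions of the validation
studies: β₃ recovery uses 4 × 5000 pooled draws (δ = 0.01, 200 posterior
samples) on a 128-tip tree; credible-interval coverage uses 20 reruns of
2000 draws (δ = 0.025) on 32 tips; cross-validation uses 500 reference
rows per model (δ = 0.1, mnlogistic) with 100 validations. Monte Carlo
test bands are 3 standard errors at 10⁴ replicates; the Euler–Maruyama
oracle uses dt = 2.5e−4–5e−4.

## What the synthetic data do and do not show

The generator reproduces the study conditions exactly: Gaussian/OU
covariates, a noiseless optimum link, contemporaneous tips, correct
trees, and one trait pair per tree. Real comparative data add
measurement error, tree misspecification, non-ultrametric sampling and
within-species variation, none of which are modeled; passing tests
demonstrate correctness of the machinery under the models' own
assumptions, not robustness to their violation.

## Known limitations

- **Model-choice power is intrinsically limited under the default
  priors.** With α_x ~ U(0, 0.25) on a unit-height tree the OU covariate
  deflates tip variance by a factor ≥ 0.78 relative to BM and is fully
  confounded with the unknown σ_x, so OUBM/OUOU (and OUGBM/OUGOU) largely
  overlap in summary space: a gradient-boosted classifier trained on an
  8000-row reference table reaches only ~36% four-way accuracy (~50%
  within each pair), and leave-one-out ABC model choice recovers the true
  OUOU model in roughly 30–60 of 100 validations depending on method and
  tolerance. Larger reference tables improve this only slowly. Users who
  need reliable covariate-dynamics selection should use stronger priors
  on α_x or longer (unscaled) time spans.
- Exact simulation of integrated geometric BM (Laplace-transform methods)
  is out of scope; quadrature on a discretized path is used instead.
- The half-minimum exponential baseline fixes β₁ = min(y)/2 by
  construction; it is a quick anchor, not a joint nonlinear LS fit, and
  whether its RMSD is computed before or after any feature scaling is a
  user choice (the package computes it on whatever scale it is given).
- Uncertainty is not propagated from posterior samples through the
  optimum-change calculus (point posterior means are interpreted, as in
  the published analysis).
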
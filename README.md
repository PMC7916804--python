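# phyloabc

Phylogenetic adaptive-trait evolution with **curved optimal regression**:
simulation and likelihood-free (ABC) inference for a response trait under
stabilizing selection whose optimum tracks a covariate trait, linearly or
exponentially, along a phylogeny.

## The models

A response trait *y* evolves along every branch of a rooted, unit-height
phylogeny as an Ornstein–Uhlenbeck (OU) process

    dy_t = α_y (θ_t − y_t) dt + σ_y dW_t^y ,

pulled with force α_y toward a *moving* optimum θ_t that is a deterministic
function of a covariate trait *x*:

| model | optimum θ_t            | covariate dynamics                          |
|-------|------------------------|---------------------------------------------|
| OUBM  | β₁ + β₂ x_t            | Brownian motion, dx = σ_x dW^x               |
| OUOU  | β₁ + β₂ x_t            | OU, dx = α_x(θ_x − x)dt + σ_x dW^x           |
| OUGBM | β₁ + β₂ exp(β₃ x_t)    | Brownian motion                              |
| OUGOU | β₁ + β₂ exp(β₃ x_t)    | OU                                           |

Under the exponential ("geometric") optima, the OU solution for y contains
the time integral of a geometric Brownian/OU process,

    A_t = e^{−α_y t} ∫₀ᵗ α_y e^{α_y s} θ_s ds ,

which has no closed form. The engine therefore samples an exact covariate
path on a per-branch grid and evaluates A_t by composite Simpson quadrature
on that same path, preserving the covariate–response dependence; internal
node states are inherited by both daughter branches. Since the likelihood
is intractable, inference is rejection ABC: parameters are drawn from
priors, trait pairs are simulated down the tree, and draws are accepted by
the Euclidean distance between 24 summary statistics (per trait: mean,
median, sd, skewness, kurtosis, four contrast moments, Blomberg's K,
Pagel's λ, and the GLS phylogenetic mean). Model choice uses posterior
model probabilities (accepted-label frequencies or multinomial logistic
regression) and their ratios, the Bayes factors.

Who it is for: comparative biologists who suspect the optimum of a trait
responds *nonlinearly* to a covariate (e.g. body mass vs bone
circumference on the log scale) and want simulation-based inference and
model comparison beyond linear phylogenetic regression.

## Worked example

Simulate an OUGBM dataset on a 32-tip balanced Grafen tree, then infer
parameters and compare all four models:

```bash
phyloabc fixtures --kind balanced --n-tips 32 --model OUGBM --seed 11 --out-dir demo
```

```python
import phyloabc as pa
from phyloabc.abc import ABCConfig, model_posteriors

tree = pa.read_newick(open("demo/fixture_tree.nwk").read())
data = pa.read_trait_csv("demo/fixture_traits.csv")
calc = pa.SummaryCalculator(tree)
s0 = calc.summary_matrix(data.y, data.x)[0]

priors = {m: pa.default_uniform_priors(m) for m in pa.MODELS}
table = pa.build_reference_table(list(pa.MODELS), tree, priors,
                                 n_draws=2000, seed=1, calc=calc)
accepted = pa.abc_reject(s0, table, ABCConfig(delta=0.01))
print(pa.posterior_summary(accepted).round(3))
```

prints (the fixture was generated at α_y=0.5, σ_x=2.5, σ_y=1,
β=(0, 1, −0.5)):

```
          mean   q2.5  q97.5
alpha_y  0.491  0.032  0.975
alpha_x  0.117  0.004  0.225
theta_x -0.282 -4.424  4.707
sigma_x  2.428  0.205  4.696
sigma_y  0.931  0.056  1.925
beta1   -0.114 -0.956  0.946
beta2    1.089  0.030  1.944
beta3   -0.526 -0.981 -0.027
```

Posterior means sit near the generating values; the wide credible
intervals reflect the deliberately broad uniform priors. Finally, the
interpretation layer converts covariate changes into optimum changes. For
the published exponential fit of kangaroo body mass on femoral
circumference (β₂ = 0.2946, β₃ = 0.4251):

```bash
phyloabc interpret --model exponential --beta2 0.2946 --beta3 0.4251 --ratio 1.05
# optimum ratio: 1.0062
# percent change: +0.62%
```

i.e. a 5% increase in bone circumference shifts the body-mass optimum up
by 0.62%.

The CLI also provides `simulate`, `stats`, `infer` (YAML-configured ABC
run writing posterior samples, model probabilities and a Bayes-factor
table), `cv` (leave-one-out model-choice cross-validation) and `fit`
(non-phylogenetic linear and half-minimum exponential baselines with
RMSD).

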
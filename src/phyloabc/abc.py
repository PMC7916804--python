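"""Rejection ABC, model posterior probabilities, Bayes factors and
leave-one-out cross-validation for the four adaptive-trait models.

The rejection sampler follows the classic recipe: draw parameters from the
prior, simulate a trait pair down the tree, summarize, and accept the
delta-fraction of draws whose summary vectors are closest (Euclidean) to
the observed one.  Because the raw statistics live on wildly different
scales, each component is divided by its median absolute deviation across
the reference table by default (``standardize="mad"``); ``"raw"`` gives
the unscaled Euclidean norm.

Model choice treats the model label as one more parameter with a uniform
prior over the candidate set: the posterior probability of a model is the
fraction of accepted rows carrying its label ("rejection"), or the
predicted class probability of a multinomial logistic regression fitted on
the accepted rows ("mnlogistic").  Bayes factors are ratios of posterior
model probabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models as _models
from . import sde
from .phylo import Phylogeny
from .sumstats import DEFAULT_STATS, SummaryCalculator

__all__ = [
    "ABCConfig",
    "ReferenceTable",
    "PosteriorSamples",
    "BFTable",
    "ConfusionMatrix",
    "distance",
    "mad_scales",
    "abc_reject",
    "model_posteriors",
    "bayes_factor_table",
    "build_reference_table",
    "posterior_summary",
    "cross_validate",
]

ALL_PARAMS = ("alpha_y", "alpha_x", "theta_x", "sigma_x", "sigma_y",
              "beta1", "beta2", "beta3")


@dataclass
class ABCConfig:
    """Rejection-ABC settings.

    n_draws : prior draws per model (L).
    delta : acceptance proportion in (0, 1]; ceil(total * delta) rows with
        the smallest distances are kept.
    standardize : "mad" (componentwise median-absolute-deviation scaling
        computed on the reference table) or "raw".
    """

    n_draws: int = 50_000
    delta: float = 0.01
    standardize: str = "mad"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.delta <= 1):
            raise ValueError("delta must be in (0, 1]")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.standardize not in ("mad", "raw"):
            raise ValueError("standardize must be 'mad' or 'raw'")


@dataclass
class ReferenceTable:
    """Simulated (model label, parameter draw, summary vector) rows."""

    model: np.ndarray
    params: pd.DataFrame
    summaries: np.ndarray
    stat_names: list[str]
    seed: int | None = None

    def __post_init__(self):
        self.model = np.asarray(self.model)
        self.summaries = np.asarray(self.summaries, float)
        if not (len(self.model) == len(self.params) == self.summaries.shape[0]):
            raise ValueError("table components must have equal row counts")

    def __len__(self) -> int:
        return self.summaries.shape[0]


@dataclass
class PosteriorSamples:
    """Accepted draws, ordered by nondecreasing distance."""

    model: np.ndarray
    params: pd.DataFrame
    distances: np.ndarray


@dataclass
class BFTable:
    """Posterior model probabilities and the pairwise Bayes-factor matrix,
    both ordered by descending probability."""

    probabilities: pd.Series
    bayes_factors: pd.DataFrame


@dataclass
class ConfusionMatrix:
    """counts.loc[true_model, selected_model] over validation replicates."""

    counts: pd.DataFrame

    def correct(self, model_id: str) -> int:
        return int(self.counts.loc[model_id, model_id])


# ----------------------------------------------------------------------
# distances
# ----------------------------------------------------------------------

def mad_scales(summaries: np.ndarray) -> np.ndarray:
    """Median absolute deviation per statistic; exact zeros replaced by 1
    so constant columns do not blow up the scaled distance."""
    S = np.asarray(summaries, float)
    mad = np.median(np.abs(S - np.median(S, axis=0)), axis=0)
    return np.where(mad > 0, mad, 1.0)


def distance(S0, S, scales=None) -> np.ndarray:
    """Euclidean distance between the observed vector and table rows,
    componentwise divided by ``scales`` when given."""
    S0 = np.asarray(S0, float)
    single = np.asarray(S).ndim == 1
    S = np.atleast_2d(np.asarray(S, float))
    if S.shape[1] != S0.size:
        raise ValueError("summary length mismatch")
    diff = S - S0
    if scales is not None:
        scales = np.asarray(scales, float)
        if np.any(scales <= 0):
            raise ValueError("scales must be positive")
        diff = diff / scales
    d = np.sqrt(np.einsum("rj,rj->r", diff, diff))
    return float(d[0]) if single else d


def _scaled_distances(S0, table: ReferenceTable, cfg: ABCConfig) -> np.ndarray:
    scales = mad_scales(table.summaries) if cfg.standardize == "mad" else None
    return distance(S0, table.summaries, scales)


# ----------------------------------------------------------------------
# rejection sampler and model choice
# ----------------------------------------------------------------------

def abc_reject(S0, table: ReferenceTable, cfg: ABCConfig) -> PosteriorSamples:
    """Accept the ceil(total * delta) reference rows closest to S0
    (ties broken by row index)."""
    if len(table) == 0:
        raise ValueError("empty reference table")
    d = _scaled_distances(S0, table, cfg)
    k = int(math.ceil(len(table) * cfg.delta))
    order = np.argsort(d, kind="stable")[:k]
    return PosteriorSamples(table.model[order],
                            table.params.iloc[order].reset_index(drop=True),
                            d[order])


def model_posteriors(S0, table: ReferenceTable, cfg: ABCConfig,
                     method: str = "rejection") -> dict[str, float]:
    """Posterior model probabilities from the accepted rows (uniform model
    prior, equal draws per model)."""
    model_ids = list(dict.fromkeys(table.model.tolist()))
    if len(model_ids) < 1:
        raise ValueError("reference table covers no models")
    accepted = abc_reject(S0, table, cfg)
    if len(accepted.distances) == 0:
        raise ValueError("no accepted samples")
    if method == "rejection":
        labels, counts = np.unique(accepted.model, return_counts=True)
        freq = dict(zip(labels.tolist(), counts / counts.sum()))
        return {m: float(freq.get(m, 0.0)) for m in model_ids}
    if method == "mnlogistic":
        return _mnlogistic_posteriors(S0, table, cfg, model_ids)
    raise ValueError(f"unknown model-choice method {method!r}")


def _mnlogistic_posteriors(S0, table, cfg, model_ids):
    """Multinomial logistic regression on the accepted rows, evaluated at
    the observed summary vector (the regression-based model-choice
    estimator used for cross-validation)."""
    from sklearn.linear_model import LogisticRegression

    scales = mad_scales(table.summaries) if cfg.standardize == "mad" else \
        np.ones(table.summaries.shape[1])
    d = distance(S0, table.summaries, scales)
    k = int(math.ceil(len(table) * cfg.delta))
    order = np.argsort(d, kind="stable")[:k]
    ylab = table.model[order]
    present = list(dict.fromkeys(ylab.tolist()))
    if len(present) == 1:
        return {m: float(m == present[0]) for m in model_ids}
    Xf = (table.summaries[order] - np.asarray(S0, float)) / scales
    clf = LogisticRegression(max_iter=2000, C=1.0)
    clf.fit(Xf, ylab)
    probs = clf.predict_proba(np.zeros((1, Xf.shape[1])))[0]
    out = {m: 0.0 for m in model_ids}
    out.update({m: float(p) for m, p in zip(clf.classes_, probs)})
    return out


def bayes_factor_table(probs) -> BFTable:
    """Pairwise Bayes factors BF[i, j] = P(Mi|D) / P(Mj|D), ranked by
    descending posterior probability."""
    s = pd.Series(probs, dtype=float)
    if np.any(s < 0) or not np.isclose(s.sum(), 1.0, atol=1e-6):
        raise ValueError("probabilities must be nonnegative and sum to 1")
    s = s.sort_values(ascending=False)
    if np.any(s.values == 0):
        warnings.warn("zero posterior probability: some Bayes factors are infinite")
    with np.errstate(divide="ignore", invalid="ignore"):
        bf = np.divide.outer(s.values, s.values)
    np.fill_diagonal(bf, 1.0)
    return BFTable(s, pd.DataFrame(bf, index=s.index, columns=s.index))


# ----------------------------------------------------------------------
# reference tables and posterior summaries
# ----------------------------------------------------------------------

def build_reference_table(model_ids, tree: Phylogeny, priors, n_draws: int,
                          seed: int, calc: SummaryCalculator | None = None,
                          stats=DEFAULT_STATS, root: sde.RootState | None = None,
                          grid: sde.GridConfig = sde.GridConfig(),
                          batch_size: int = 5000) -> ReferenceTable:
    """Prior-predictive reference table on a fixed tree.

    ``priors`` is a PriorSpec or a mapping model_id -> PriorSpec; ``n_draws``
    rows are simulated per model in vectorized batches.
    """
    if isinstance(model_ids, str):
        model_ids = [model_ids]
    root = root or sde.RootState()
    calc = calc or SummaryCalculator(tree, stats=stats)
    ss = np.random.SeedSequence(int(seed))
    sub = ss.generate_state(2 * len(model_ids)) % (2**31)
    labels, frames, summaries = [], [], []
    for mi, model_id in enumerate(model_ids):
        spec = priors[model_id] if isinstance(priors, dict) else priors
        rng = np.random.default_rng(int(sub[2 * mi]))
        draws = spec.sample(rng, size=n_draws)
        done = 0
        while done < n_draws:
            hi = min(done + batch_size, n_draws)
            chunk = {k: v[done:hi] for k, v in draws.items()}
            X, Y = _models.simulate_tips_batch(
                model_id, chunk, tree, int(sub[2 * mi + 1]) + done,
                rho_y=root.rho_y, rho_x=root.rho_x, grid=grid)
            summaries.append(calc.summary_matrix(Y, X))
            done = hi
        df = pd.DataFrame({k: draws[k] for k in spec.param_names})
        frames.append(df.reindex(columns=ALL_PARAMS))
        labels.extend([model_id] * n_draws)
    params = pd.concat(frames, ignore_index=True)
    return ReferenceTable(np.array(labels), params, np.vstack(summaries),
                          calc.names(), seed=int(seed))


def posterior_summary(samples: PosteriorSamples,
                      ci: float = 0.95) -> pd.DataFrame:
    """Posterior mean and equal-tailed credible interval per parameter."""
    lo, hi = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100
    rows = {}
    for col in samples.params.columns:
        v = samples.params[col].dropna().to_numpy(float)
        if v.size == 0:
            continue
        rows[col] = {"mean": v.mean(),
                     f"q{lo:g}": np.percentile(v, lo),
                     f"q{hi:g}": np.percentile(v, hi)}
    return pd.DataFrame(rows).T


# ----------------------------------------------------------------------
# cross-validation
# ----------------------------------------------------------------------

def cross_validate(model_ids, tree_generator, n_val: int, cfg: ABCConfig,
                   method: str = "mnlogistic", n_ref: int = 500,
                   priors=None, validate_models=None,
                   root: sde.RootState | None = None,
                   grid: sde.GridConfig = sde.GridConfig()) -> ConfusionMatrix:
    """Leave-one-out ABC model-choice cross-validation.

    ``tree_generator(rng)`` must return a (unit-height) Phylogeny; a fresh
    tree is drawn for every reference row, so tree variability is part of
    the prior predictive.  For each of the first ``n_val`` rows of every
    validated model, the row is held out, classified against all remaining
    rows, and the counts of (true, selected) pairs are returned.

    ``method`` is "mnlogistic" (multinomial logistic regression on the
    accepted set, the method used for the published confusion matrices) or
    "rejection" (accepted-label frequencies).
    """
    if isinstance(model_ids, str):
        model_ids = [model_ids]
    validate_models = list(validate_models or model_ids)
    if n_val < 1 or n_val > n_ref:
        raise ValueError("need 1 <= n_val <= n_ref")
    root = root or sde.RootState()
    rng = np.random.default_rng(int(cfg.seed) % (2**31))
    labels, summaries = [], []
    for model_id in model_ids:
        spec = (priors[model_id] if isinstance(priors, dict)
                else priors) or _models.default_uniform_priors(model_id)
        for _ in range(n_ref):
            tree = tree_generator(rng)
            calc = SummaryCalculator(tree)
            draw = spec.sample(rng)
            X, Y = _models.simulate_tips_batch(
                model_id, {k: np.atleast_1d(v) for k, v in draw.items()},
                tree, int(rng.integers(2**31)),
                rho_y=root.rho_y, rho_x=root.rho_x, grid=grid)
            summaries.append(calc.summary_matrix(Y, X)[0])
            labels.append(model_id)
    S = np.vstack(summaries)
    labels = np.array(labels)
    scales = mad_scales(S) if cfg.standardize == "mad" else None

    counts = pd.DataFrame(0, index=validate_models, columns=list(model_ids))
    idx_of = {m: np.flatnonzero(labels == m) for m in model_ids}
    for true_model in validate_models:
        for row in idx_of[true_model][:n_val]:
            keep = np.ones(len(labels), bool)
            keep[row] = False
            sub = ReferenceTable(labels[keep],
                                 pd.DataFrame(index=np.arange(keep.sum())),
                                 S[keep], [], seed=None)
            sub_cfg = ABCConfig(n_draws=cfg.n_draws, delta=cfg.delta,
                                standardize=cfg.standardize, seed=cfg.seed)
            probs = model_posteriors(S[row], sub, sub_cfg, method=method)
            selected = max(probs, key=probs.get)
            counts.loc[true_model, selected] += 1
    return ConfusionMatrix(counts)
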
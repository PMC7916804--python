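"""Per-branch transition sampling for the four adaptive-trait models.

The response trait y follows an Ornstein-Uhlenbeck (OU) process
``dy = alpha_y (theta_t - y) dt + sigma_y dW^y`` whose optimum theta_t is a
deterministic function of a covariate x evolving as Brownian motion (BM) or
OU:

    linear      theta_t = beta1 + beta2 * x_t          (OUBM, OUOU)
    exponential theta_t = beta1 + beta2 * exp(beta3 x_t)  (OUGBM, OUGOU)

Integrating the OU solution gives, over a branch of length t,

    y_t = e^{-a t} y_0 + A_t + N(0, sigma_y^2 (1 - e^{-2 a t})/(2 a)),
    A_t = e^{-a t} \\int_0^t a e^{a s} theta_s ds,   a = alpha_y.

The time integral A_t has no closed form for the exponential (geometric)
optima, so every model is simulated by one path-based engine: a covariate
path is drawn exactly on a per-branch grid and the optimum integral is
evaluated by composite Simpson quadrature on that same path, which keeps the
branch-end covariate and the A term correctly correlated.  Closed-form
Gaussian expressions exist for the linear models and serve as test oracles.

All times are in scaled units (tree height 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MODELS",
    "LINEAR_MODELS",
    "EXPONENTIAL_MODELS",
    "BM_COVARIATE_MODELS",
    "OU_COVARIATE_MODELS",
    "ModelParams",
    "RegressionParams",
    "RootState",
    "BranchPath",
    "GridConfig",
    "edge_grid",
    "bm_step",
    "ou_step",
    "sample_bm_path",
    "sample_ou_path",
    "gbm_time_integral",
    "gou_time_integral",
    "a_term",
    "y_step",
    "ou_variance",
]

MODELS = ("OUBM", "OUOU", "OUGBM", "OUGOU")
LINEAR_MODELS = ("OUBM", "OUOU")
EXPONENTIAL_MODELS = ("OUGBM", "OUGOU")
BM_COVARIATE_MODELS = ("OUBM", "OUGBM")
OU_COVARIATE_MODELS = ("OUOU", "OUGOU")


@dataclass
class ModelParams:
    """Diffusion parameters.

    alpha_y : selection force on the response (1/time), > 0.
    alpha_x : selection force on the covariate (1/time); OU-covariate
        models only.
    theta_x : covariate optimum (trait units); OU-covariate models only.
    sigma_x : covariate diffusion rate (trait / sqrt(time)), > 0.
    sigma_y : response diffusion rate (trait / sqrt(time)), > 0.
    """

    alpha_y: float
    sigma_x: float
    sigma_y: float
    alpha_x: float | None = None
    theta_x: float | None = None

    def validate(self, model_id: str) -> None:
        if not np.all(np.asarray(self.alpha_y) > 0):
            raise ValueError("alpha_y must be > 0")
        # sigma = 0 is admitted as the deterministic (noise-free) limit
        for name in ("sigma_x", "sigma_y"):
            if not np.all(np.asarray(getattr(self, name)) >= 0):
                raise ValueError(f"{name} must be >= 0")
        if model_id in OU_COVARIATE_MODELS:
            if self.alpha_x is None or self.theta_x is None:
                raise ValueError(f"{model_id} requires alpha_x and theta_x")
            if not np.all(np.asarray(self.alpha_x) > 0):
                raise ValueError("alpha_x must be > 0")


@dataclass
class RegressionParams:
    """Optimal-regression coefficients: theta = beta1 + beta2 * g(x).

    beta3 (the exponent rate in g(x) = exp(beta3 x)) is used only by the
    exponential models and must be nonzero there.
    """

    beta1: float
    beta2: float
    beta3: float | None = None

    def validate(self, model_id: str) -> None:
        for name in ("beta1", "beta2"):
            if not np.all(np.isfinite(np.asarray(getattr(self, name), float))):
                raise ValueError(f"{name} must be finite")
        if model_id in EXPONENTIAL_MODELS:
            if self.beta3 is None or not np.all(np.isfinite(np.asarray(self.beta3, float))):
                raise ValueError(f"{model_id} requires a finite beta3")


@dataclass
class RootState:
    """Initial values at the root: response, covariate and (reported-only)
    optimum.  The optimum is a deterministic function of the covariate, so
    rho_theta is carried for reporting but never simulated."""

    rho_y: float = 0.0
    rho_x: float = 0.0
    rho_theta: float = 0.0


@dataclass
class BranchPath:
    """A covariate path on a uniform grid over one branch.

    times : (m+1,) grid 0 = s_0 < ... < s_m = t (m even).
    x : (..., m+1) covariate values; x[..., 0] is the branch-start value.
    wiener : (..., m+1) standard Wiener values driving x (W_0 = 0), kept so
        integrands written directly in terms of W can reuse the same noise;
        None for OU paths (the exact OU transition consumes the noise).
    """

    times: np.ndarray
    x: np.ndarray
    wiener: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.times, float)
        if t.ndim != 1 or t.size < 3 or np.any(np.diff(t) <= 0) or t[0] != 0:
            raise ValueError("times must be strictly increasing from 0")
        if (t.size - 1) % 2 != 0:
            raise ValueError("Simpson quadrature needs an even number of grid intervals")

    @property
    def t(self) -> float:
        return float(self.times[-1])


@dataclass
class GridConfig:
    """Simpson grid density: intervals per unit of scaled branch length,
    with a floor so short branches are still resolved."""

    per_unit: int = 100
    minimum: int = 10


def edge_grid(t: float, grid: GridConfig = GridConfig()) -> int:
    """Even number of Simpson intervals for a branch of length t."""
    m = max(grid.minimum, int(math.ceil(grid.per_unit * t)))
    return m + (m % 2)


def _simpson_weights(times: np.ndarray) -> np.ndarray:
    m = times.size - 1
    if m % 2 != 0:
        raise ValueError("Simpson quadrature needs an even number of intervals")
    h = times[1] - times[0]
    w = np.full(m + 1, 2.0)
    w[1::2] = 4.0
    w[0] = w[-1] = 1.0
    return w * (h / 3.0)


def ou_variance(alpha, t):
    """(1 - e^{-2 alpha t}) / (2 alpha), with the alpha -> 0 limit t."""
    alpha = np.asarray(alpha, float)
    at = alpha * t
    safe = np.where(at > 1e-12, alpha, 1.0)
    return np.where(at > 1e-12, -np.expm1(-2.0 * safe * t) / (2.0 * safe), t)


# ----------------------------------------------------------------------
# single-step transitions
# ----------------------------------------------------------------------

def _draw(noise, rng, shape):
    if noise is not None:
        return np.asarray(noise, float)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return rng.standard_normal(shape)


def bm_step(x0, sigma_x, t, noise=None, rng=None):
    """Exact BM transition: x_t ~ N(x0, sigma_x^2 t)."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")
    x0 = np.asarray(x0, float)
    z = _draw(noise, rng, np.shape(x0))
    return x0 + np.asarray(sigma_x, float) * np.sqrt(t) * z


def ou_step(x0, alpha_x, theta_x, sigma_x, t, noise=None, rng=None):
    """Exact OU transition: mean theta + e^{-alpha t}(x0 - theta),
    variance sigma^2 (1 - e^{-2 alpha t}) / (2 alpha)."""
    if np.any(np.asarray(alpha_x) <= 0):
        raise ValueError("alpha_x must be > 0")
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")
    x0 = np.asarray(x0, float)
    decay = np.exp(-np.asarray(alpha_x) * t)
    sd = np.asarray(sigma_x) * np.sqrt(ou_variance(alpha_x, t))
    z = _draw(noise, rng, np.shape(x0))
    return theta_x + decay * (x0 - theta_x) + sd * z


def y_step(y0, a_sample, alpha_y, sigma_y, t, noise=None, rng=None):
    """Response transition: e^{-alpha_y t} y0 + A + independent OU noise."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")
    var = np.asarray(sigma_y) ** 2 * ou_variance(alpha_y, t)
    if np.any(var < 0):
        raise RuntimeError("negative response variance (internal error)")
    z = _draw(noise, rng, np.shape(np.asarray(y0, float)))
    return np.exp(-np.asarray(alpha_y) * t) * np.asarray(y0, float) + a_sample + np.sqrt(var) * z


# ----------------------------------------------------------------------
# path sampling
# ----------------------------------------------------------------------

def sample_bm_path(x0, sigma_x, t, m=None, rng=None, grid=GridConfig()) -> BranchPath:
    """BM covariate path on a uniform grid; x_s = x0 + sigma_x W_s."""
    m = edge_grid(t, grid) if m is None else m
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    times = np.linspace(0.0, t, m + 1)
    x0 = np.asarray(x0, float)
    h = t / m
    incr = rng.standard_normal(np.shape(x0) + (m,)) * math.sqrt(h)
    W = np.concatenate([np.zeros(np.shape(x0) + (1,)), np.cumsum(incr, axis=-1)], axis=-1)
    x = x0[..., None] + np.asarray(sigma_x, float)[..., None] * W
    return BranchPath(times, np.squeeze(x) if x0.ndim == 0 else x,
                      np.squeeze(W) if x0.ndim == 0 else W)


def sample_ou_path(x0, alpha_x, theta_x, sigma_x, t, m=None, rng=None,
                   grid=GridConfig()) -> BranchPath:
    """OU covariate path sampled exactly at each grid point."""
    m = edge_grid(t, grid) if m is None else m
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    times = np.linspace(0.0, t, m + 1)
    h = t / m
    x0 = np.asarray(x0, float)
    alpha_x = np.asarray(alpha_x, float)
    phi = np.exp(-alpha_x * h)
    sd = np.asarray(sigma_x, float) * np.sqrt(ou_variance(alpha_x, h))
    x = np.empty(np.shape(x0) + (m + 1,))
    x[..., 0] = x0
    z = rng.standard_normal(np.shape(x0) + (m,))
    for k in range(m):
        x[..., k + 1] = theta_x + phi * (x[..., k] - theta_x) + sd * z[..., k]
    return BranchPath(times, x, None)


# ----------------------------------------------------------------------
# time integrals of the (geometric) optimum
# ----------------------------------------------------------------------

def gbm_time_integral(a, b, t, path: BranchPath):
    """Simpson estimate of int_0^t exp(a s + b W_s) ds on the path's
    Wiener values.  The integrand is a geometric Brownian motion; there is
    no closed form, but E = (e^{(a + b^2/2) t} - 1)/(a + b^2/2)."""
    if path.wiener is None:
        raise ValueError("path does not carry Wiener values")
    if not math.isclose(path.t, t, rel_tol=1e-9):
        raise ValueError("path grid does not span [0, t]")
    w = _simpson_weights(path.times)
    a = np.asarray(a, float)[..., None]
    b = np.asarray(b, float)[..., None]
    integrand = np.exp(a * path.times + b * path.wiener)
    return integrand @ w


def gou_time_integral(alpha_y, beta3, x_path: BranchPath, theta_exponent_fn=None):
    """Simpson estimate of int_0^t e^{alpha_y s} exp(beta3 x_s) ds on a
    covariate path (the geometric-OU time integral when x is OU)."""
    w = _simpson_weights(x_path.times)
    if theta_exponent_fn is None:
        g = np.exp(np.asarray(beta3, float)[..., None] * x_path.x)
    else:
        g = theta_exponent_fn(x_path.x)
    weight = np.exp(np.asarray(alpha_y, float)[..., None] * x_path.times)
    return (weight * g) @ w


def a_term(model_id, mp: ModelParams, rp: RegressionParams, t, x0,
           path: BranchPath | None):
    """The optimum time-integral A and branch-end covariate from one path.

    A = beta1 (1 - e^{-a t}) + beta2 a e^{-a t} int_0^t e^{a s} g(x_s) ds,
    with g(x) = x for the linear models and g(x) = exp(beta3 x) for the
    exponential ones.  Returns (A, x_t) computed from the SAME path so the
    covariate-response dependence is preserved.
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}")
    ay = np.asarray(mp.alpha_y, float)
    if np.ndim(t) == 0 and float(t) == 0.0:
        shape = np.broadcast_shapes(np.shape(ay), np.shape(np.asarray(x0)))
        return np.zeros(shape), np.asarray(x0, float) + np.zeros(shape)
    if path is None:
        raise ValueError("a nonzero branch requires a covariate path")
    if not np.allclose(path.x[..., 0], x0):
        raise ValueError("path start inconsistent with x0")
    times = path.times
    w = _simpson_weights(times)
    if model_id in EXPONENTIAL_MODELS:
        g = np.exp(np.asarray(rp.beta3, float)[..., None] * path.x)
    else:
        g = path.x
    weight = np.exp(ay[..., None] * times)
    integral = (weight * g) @ w
    decay = np.exp(-ay * t)
    A = np.asarray(rp.beta1, float) * (-np.expm1(-ay * t)) \
        + np.asarray(rp.beta2, float) * ay * decay * integral
    return A, path.x[..., -1]
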
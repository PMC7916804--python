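"""Non-phylogenetic baseline fits: half-minimum exponential least squares,
ordinary linear least squares, RMSD, and min-max feature scaling.

The exponential fit y = beta1 + beta2 * exp(beta3 * x) fixes the offset at
beta1 = min(y)/2 (a cheap, robust anchor below the data), then estimates
(beta2, beta3) by ordinary least squares on the linearized model
log(y - beta1) = log(beta2) + beta3 * x.  This is the standard quick
baseline for convex trait relationships; it is not a full nonlinear
least-squares fit over all three coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CurveFit", "fit_exponential_halfmin", "fit_linear_ls",
           "rmsd", "feature_scale"]


@dataclass
class CurveFit:
    """A fitted baseline curve: form 'linear' or 'exponential',
    coefficients, and the data-scale RMSD of its predictions."""

    form: str
    coefficients: dict[str, float]
    rmsd: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        c = self.coefficients
        if self.form == "linear":
            return c["intercept"] + c["slope"] * x
        return c["beta1"] + c["beta2"] * np.exp(c["beta3"] * x)


def rmsd(y, y_hat) -> float:
    """Root mean square deviation sqrt(mean((y - y_hat)^2))."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def fit_linear_ls(x, y) -> CurveFit:
    """Ordinary least-squares line fit."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need at least two distinct x values")
    A = np.column_stack([np.ones_like(x), x])
    (b0, b1), *_ = np.linalg.lstsq(A, y, rcond=None)
    fit = CurveFit("linear", {"intercept": float(b0), "slope": float(b1)}, 0.0)
    fit.rmsd = rmsd(y, fit.predict(x))
    return fit


def fit_exponential_halfmin(x, y) -> CurveFit:
    """Half-minimum exponential fit: beta1 = min(y)/2, then OLS of
    log(y - beta1) on x for (log beta2, beta3).  RMSD is computed on the
    original y scale."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    if y.min() <= 0:
        raise ValueError("all responses must be positive (log precondition)")
    beta1 = float(y.min()) / 2.0
    z = np.log(y - beta1)
    A = np.column_stack([np.ones_like(x), x])
    (logb2, b3), *_ = np.linalg.lstsq(A, z, rcond=None)
    fit = CurveFit("exponential",
                   {"beta1": beta1, "beta2": float(np.exp(logb2)),
                    "beta3": float(b3)}, 0.0)
    fit.rmsd = rmsd(y, fit.predict(x))
    return fit


def feature_scale(v) -> np.ndarray:
    """Min-max scaling to [0, 1]; order statistics are preserved."""
    v = np.asarray(v, float)
    if np.ptp(v) == 0:
        raise ValueError("cannot feature-scale a constant vector")
    return (v - v.min()) / (v.max() - v.min())
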
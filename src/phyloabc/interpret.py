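"""Translating covariate percentage changes into optimum percentage changes.

Traits are analyzed on a log scale, so changes are read as ratios.  For an
optimal linear regression theta = beta1 + beta2 * x the log-scale identity
log(theta2/theta1) = beta2 * log(x2/x1) gives

    theta2 / theta1 = (x2 / x1) ** beta2,

independent of the reference point.  For an optimal exponential regression
theta = beta1 + beta2 * exp(beta3 * x) the same algebra gives

    theta2 / theta1 = exp(beta2 * (x2**beta3 - x1**beta3)),

which depends on the reference covariate x1 (default 1, the conventional
reporting point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RatioChange", "linear_optimum_ratio", "exponential_optimum_ratio"]


@dataclass
class RatioChange:
    """A multiplicative optimum change and its percent equivalent."""

    ratio: float

    def __post_init__(self):
        if not (self.ratio > 0):
            raise ValueError("ratio must be positive")

    @property
    def percent(self) -> float:
        return (self.ratio - 1.0) * 100.0

    def percent_rounded(self, ndigits: int = 2) -> float:
        return round(self.percent, ndigits)


def linear_optimum_ratio(beta2: float, r: float) -> RatioChange:
    """Optimum ratio theta2/theta1 = r**beta2 when the covariate changes by
    the factor r = x2/x1 under a linear optimal regression."""
    if not (r > 0):
        raise ValueError("covariate ratio r must be positive")
    return RatioChange(float(r) ** float(beta2))


def exponential_optimum_ratio(beta2: float, beta3: float, x1: float,
                              r: float) -> RatioChange:
    """Optimum ratio exp(beta2 * ((r*x1)**beta3 - x1**beta3)) under an
    exponential optimal regression; depends on the reference point x1."""
    if not (x1 > 0):
        raise ValueError("reference covariate x1 must be positive")
    if not (r > 0):
        raise ValueError("covariate ratio r must be positive")
    x2 = r * x1
    return RatioChange(float(np.exp(beta2 * (x2 ** beta3 - x1 ** beta3))))
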
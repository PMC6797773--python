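"""Cross-cutting regression analyses.

Two analyses relate dispersal to covariates: a logarithmic regression of
per-species mean vertical dispersal distance on home-range size
(y = slope·ln x + intercept), and per-species linear regressions of
per-seed dispersal distance on inferred mother-plant altitude.  Results
carry the signed Pearson r, the t statistic t = r·√((n−2)/(1−r²)) with
the slope's sign, and the two-sided p-value on n−2 degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = ["RegressionResult", "linear_regression", "log_regression"]


@dataclass(frozen=True)
class RegressionResult:
    model: Literal["linear", "log_linear"]
    slope: float
    intercept: float
    r: float
    t_stat: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def abs_r(self) -> float:
        """|r|; reported alongside signed r because figure conventions for
        the sign of the correlation vary."""
        return abs(self.r)


def _fit(x: np.ndarray, y: np.ndarray, model: str) -> RegressionResult:
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 observations")
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: need >= 2 distinct x values")
    if np.ptp(y) == 0.0:
        warnings.warn("response is constant: slope and r reported as 0 by convention")
        return RegressionResult(model, 0.0, float(y[0]), 0.0, 0.0, 1.0, n)
    res = stats.linregress(x, y)
    r = float(res.rvalue)
    df = n - 2
    r2 = min(r * r, 1.0)
    if r2 >= 1.0:
        t = math.copysign(math.inf, res.slope)
        p = 0.0
    else:
        t = math.copysign(abs(r) * math.sqrt(df / (1.0 - r2)), res.slope)
        p = float(2.0 * stats.t.sf(abs(t), df))
    return RegressionResult(
        model=model,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=r,
        t_stat=float(t),
        p_value=p,
        n=n,
    )


def linear_regression(
    mother_alt_m: Sequence[float], distance_m: Sequence[float]
) -> RegressionResult:
    """OLS of dispersal distance on mother-plant altitude."""
    x = np.asarray(mother_alt_m, dtype=float)
    y = np.asarray(distance_m, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    return _fit(x, y, "linear")


def log_regression(
    home_range_ha: Sequence[float], mean_distance_m: Sequence[float]
) -> RegressionResult:
    """OLS of mean dispersal distance on ln(home range).

    r is the Pearson correlation between ln(x) and y.  Home ranges must
    be strictly positive.
    """
    x = np.asarray(home_range_ha, dtype=float)
    y = np.asarray(mean_distance_m, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if np.any(x <= 0):
        raise ValueError("home ranges must be > 0 for a logarithmic model")
    return _fit(np.log(x), y, "log_linear")
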
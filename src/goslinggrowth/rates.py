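"""Haldane rates of phenotypic change and the latitude regression.

A haldane expresses the difference between two population trait means in
pooled phenotypic standard deviations per generation:

    h = (X2/Sp − X1/Sp) / g

(synchronic comparison of contemporaneous populations).  Sp is supplied
by the caller — typically a pooled SD derived from the growth models —
and g = period / generation_time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "generations",
    "haldane",
    "solve_pooled_sd",
    "HaldaneInputs",
    "latitude_regression",
    "LatitudeRegression",
]


def generations(period_years: float, generation_time_years: float) -> float:
    """Number of generations in a period: g = period / generation_time."""
    if period_years <= 0 or generation_time_years <= 0:
        raise ValueError("period and generation time must be positive")
    return period_years / generation_time_years


def haldane(X1: float, X2: float, Sp: float, g: float) -> float:
    """Rate of change in pooled-SD units per generation.

    Antisymmetric in (X1, X2); zero iff the means coincide.
    """
    if Sp <= 0:
        raise ValueError("pooled SD must be positive")
    if g <= 0:
        raise ValueError("generations must be positive")
    return (X2 / Sp - X1 / Sp) / g


def solve_pooled_sd(X1: float, X2: float, h: float, g: float) -> float:
    """Invert the haldane formula for the pooled SD: Sp = (X2 − X1)/(h·g)."""
    if h == 0:
        raise ValueError("cannot back-solve Sp for h = 0")
    if g <= 0:
        raise ValueError("generations must be positive")
    return (X2 - X1) / (h * g)


@dataclass(frozen=True)
class HaldaneInputs:
    X1: float
    X2: float
    Sp: float
    g: float

    @property
    def h(self) -> float:
        return haldane(self.X1, self.X2, self.Sp, self.g)


@dataclass
class LatitudeRegression:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    n: int
    band: pd.DataFrame  # latitude, fit, lo95, hi95


def latitude_regression(points: pd.DataFrame) -> LatitudeRegression:
    """OLS of a (mass-corrected) growth coefficient on breeding latitude.

    ``points`` needs columns ``latitude_deg`` and ``corrected_coefficient``;
    the correction for body mass is the caller's responsibility.  Returns
    slope/intercept with SEs and a 95% confidence band over the observed
    latitude range.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    x = points["latitude_deg"].to_numpy(dtype=float)
    y = points["corrected_coefficient"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("latitudes are degenerate (no spread)")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), 50)
    pred = res.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    band = pd.DataFrame(
        {
            "latitude_deg": grid,
            "fit": pred["mean"].to_numpy(),
            "lo95": pred["mean_ci_lower"].to_numpy(),
            "hi95": pred["mean_ci_upper"].to_numpy(),
        }
    )
    return LatitudeRegression(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        r_squared=float(res.rsquared),
        n=len(points),
        band=band,
    )
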
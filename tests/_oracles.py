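"""Independent oracles used only by the test suite.

Each oracle reaches the checked quantity by a different route than the
package: Meeus-style solar position (vs the NOAA Fourier series),
minute-resolution altitude scans (vs the closed-form hour angle),
golden-section search (vs Brent/Newton least squares), Gauss-Hermite
quadrature (vs the Laplace approximation) and direct generalised least
squares (vs iterative mixed-model fitting).
"""

from __future__ import annotations

import datetime as dt
from math import asin, atan2, cos, degrees, radians, sin

import numpy as np

_J2000_ORDINAL = dt.date(2000, 1, 1).toordinal()


def meeus_solar_declination(date: dt.date) -> float:
    """Low-precision Meeus ecliptic-coordinates declination, degrees."""
    d = date.toordinal() - _J2000_ORDINAL  # days from J2000 (noon-ish)
    L = (280.460 + 0.9856474 * d) % 360.0
    g = radians((357.528 + 0.9856003 * d) % 360.0)
    lam = radians(L + 1.915 * sin(g) + 0.020 * sin(2 * g))
    eps = radians(23.439 - 0.0000004 * d)
    return degrees(asin(sin(eps) * sin(lam)))


def meeus_equation_of_time(date: dt.date) -> float:
    """Equation of time in minutes from the Meeus solar position."""
    d = date.toordinal() - _J2000_ORDINAL
    L = (280.460 + 0.9856474 * d) % 360.0
    g = radians((357.528 + 0.9856003 * d) % 360.0)
    lam = radians(L + 1.915 * sin(g) + 0.020 * sin(2 * g))
    eps = radians(23.439 - 0.0000004 * d)
    alpha = degrees(atan2(cos(eps) * sin(lam), cos(lam))) % 360.0
    return 4.0 * (((L - alpha) + 180.0) % 360.0 - 180.0)


def scan_daylight_hours(
    lat: float, date: dt.date, threshold_deg: float, step_minutes: float = 1.0
) -> float:
    """Brute-force day length: count minutes with sun above the threshold."""
    delta = radians(meeus_solar_declination(date))
    phi = radians(lat)
    minutes = np.arange(0.0, 24 * 60, step_minutes)
    hour_angle = np.radians((minutes / 60.0 - 12.0) * 15.0)
    sin_alt = sin(phi) * sin(delta) + cos(phi) * cos(delta) * np.cos(hour_angle)
    above = sin_alt > sin(radians(threshold_deg))
    return float(above.sum()) * step_minutes / 60.0


def golden_section_k(y, t, A, I, lo=1e-6, hi=1.0, tol=1e-10) -> float:
    """Golden-section minimiser of the Gompertz SSR over k."""
    c = np.log(I / A)

    def ssr(k):
        r = y - A * np.exp(c * np.exp(-k * t))
        return float(r @ r)

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1, f2 = ssr(x1), ssr(x2)
    while b - a > tol:
        if f1 < f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - invphi * (b - a)
            f1 = ssr(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + invphi * (b - a)
            f2 = ssr(x2)
    return 0.5 * (a + b)


def quadrature_marginal_loglik(
    df, trait, sex, A, I, k, sd_cohort, sd_nest, sd_resid, n_nodes=40
) -> float:
    """Exact (to quadrature accuracy) marginal log-likelihood.

    Nested Gauss-Hermite integration over the scalar cohort effect and,
    inside it, each nest effect; feasible only for tiny instances.
    """
    sub = df[(df["sex"] == sex) & (df["age_days"] > 0)]
    c = np.log(I / A)
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    # physicists' rule: E[f(N(0,s^2))] = sum w_i f(sqrt(2) s x_i) / sqrt(pi)
    wn = w / np.sqrt(np.pi)
    total = 0.0
    for _, cohort_df in sub.groupby("cohort"):
        like_cohort = 0.0
        for xa, wa in zip(np.sqrt(2.0) * sd_cohort * x, wn):
            prod_nests = 1.0
            for _, nest_df in cohort_df.groupby("nest_id"):
                y = nest_df[trait].to_numpy(dtype=float)
                t = nest_df["age_days"].to_numpy(dtype=float)
                like_nest = 0.0
                for xb, wb in zip(np.sqrt(2.0) * sd_nest * x, wn):
                    mu = A * np.exp(c * np.exp(-(k + xa + xb) * t))
                    dens = np.exp(-0.5 * ((y - mu) / sd_resid) ** 2) / (
                        np.sqrt(2 * np.pi) * sd_resid
                    )
                    like_nest += wb * float(np.prod(dens))
                prod_nests *= like_nest
            like_cohort += wa * prod_nests
        total += np.log(like_cohort)
    return total


def gls_coefficients(y, X, Zc, Zn, var_c, var_n, var_e) -> np.ndarray:
    """Fixed effects by direct GLS with a fully assembled covariance."""
    V = var_e * np.eye(len(y)) + var_c * Zc @ Zc.T + var_n * Zn @ Zn.T
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
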
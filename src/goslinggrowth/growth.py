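"""Fixed-endpoint Gompertz growth models for cross-sectional biometrics.

The growth curve is the Gompertz reparameterisation pinned at both ends,

    size(t) = A * exp( ln(I/A) * exp(-k t) ),

so that size(0) = I (hatch size) and size(t) -> A (adult asymptote).  A and
I are fixed a priori from adult and hatchling measurements; only the growth
coefficient k is estimated.  Three model layers are provided:

* :func:`fit_fixed_gompertz` — k by nonlinear least squares (no random
  effects), the basis for the residual analyses.
* :func:`fit_random_gompertz` — Gaussian, mean-zero random effects on k for
  cohort (year) and nest nested within cohort; maximum likelihood with the
  random effects integrated out by a Laplace approximation.
* :func:`fit_population_contrast` — one joint random-effects model with
  treatment-coded population offsets on k, giving Wald t tests of
  between-population growth-rate differences.

Either the age-in-days axis or an accumulated-daylight-hours axis
(:func:`attach_time_axis`) can serve as the growth clock.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .daylight import CIVIL_TWILIGHT_DEG, accumulated_daylight

__all__ = [
    "GompertzParams",
    "FitResult",
    "ContrastResult",
    "gompertz_size",
    "estimate_hatch_size",
    "attach_time_axis",
    "fit_fixed_gompertz",
    "fit_random_gompertz",
    "fit_population_contrast",
]

LOG_SD_FLOOR = -10.0  # below this a variance component is flagged as boundary


# ---------------------------------------------------------------------------
# curve


def gompertz_size(A: float, I: float, k: float, t) -> np.ndarray | float:
    """Evaluate the fixed-endpoint Gompertz curve.

    Raises if I >= A (the curve would not grow towards the asymptote) or if
    any t is negative.  k = 0 degenerates to size = I for all t.
    """
    if not 0 < I < A:
        raise ValueError("require 0 < I < A")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = A * np.exp(np.log(I / A) * np.exp(-k * t))
    return out if out.shape else float(out)


@dataclass(frozen=True)
class GompertzParams:
    """(A, I, k): asymptote, hatch size and growth coefficient."""

    A: float
    I: float
    k: float

    def __post_init__(self) -> None:
        if not 0 < self.I < self.A:
            raise ValueError("require 0 < I < A")

    def size(self, t):
        return gompertz_size(self.A, self.I, self.k, t)


def estimate_hatch_size(records: pd.DataFrame, trait: str) -> float:
    """Mean trait value of goslings measured at age 0 (hatchlings)."""
    at_hatch = records.loc[records["age_days"] == 0, trait]
    if at_hatch.empty:
        raise ValueError("no age-0 records to estimate hatch size from")
    return float(at_hatch.mean())


# ---------------------------------------------------------------------------
# time axis


def attach_time_axis(
    records: pd.DataFrame,
    axis: str,
    coords: Mapping[str, tuple[float, float]] | tuple[float, float] | None = None,
    sun_altitude_threshold_deg: float = CIVIL_TWILIGHT_DEG,
) -> pd.DataFrame:
    """Return records with a growth-clock column ``t`` attached.

    ``axis="age_days"`` copies the age column; ``axis="daylight_hours"``
    computes each gosling's accumulated dawn-to-dusk hours between hatch
    and capture from colony coordinates (``coords`` is either one
    ``(lat, lon)`` pair or a mapping ``population -> (lat, lon)``), and
    also stores it as ``daylight_h``.
    """
    out = records.copy()
    if axis == "age_days":
        out["t"] = out["age_days"].astype(float)
        return out
    if axis != "daylight_hours":
        raise ValueError(f"unknown time axis {axis!r}")
    if coords is None:
        raise ValueError("daylight axis requires colony coordinates")
    if isinstance(coords, tuple):
        coords = {pop: coords for pop in out["population"].unique()}
    missing = set(out["population"].unique()) - set(coords)
    if missing:
        raise ValueError(f"missing coordinates for populations: {sorted(missing)}")
    hours = np.empty(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        lat, lon = coords[row.population]
        hours[i] = accumulated_daylight(
            lat, lon, row.hatch_date, row.capture_date, sun_altitude_threshold_deg
        )
    out["daylight_h"] = hours
    out["t"] = hours
    return out


def _time_values(records: pd.DataFrame, time_axis: str) -> np.ndarray:
    if time_axis == "age_days":
        return records["age_days"].to_numpy(dtype=float)
    if time_axis == "daylight_hours":
        if "daylight_h" not in records.columns:
            raise ValueError(
                "daylight axis requires attach_time_axis(..., 'daylight_hours') first"
            )
        return records["daylight_h"].to_numpy(dtype=float)
    raise ValueError(f"unknown time axis {time_axis!r}")


# ---------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    fixed_effects: dict[str, float]
    standard_errors: dict[str, float]
    vcov: np.ndarray | None
    variance_components: dict[str, float]
    loglik: float
    aic: float
    n_obs: int
    n_nests: int
    n_cohorts: int
    time_axis: str
    converged: bool
    boundary: list[str] = field(default_factory=list)
    trait: str = ""
    sex: str = ""
    A: float = float("nan")
    I: float = float("nan")

    @property
    def k(self) -> float:
        return self.fixed_effects["k"]

    def predict(self, t):
        return gompertz_size(self.A, self.I, self.k, t)

    def to_dict(self) -> dict:
        return {
            "fixed_effects": self.fixed_effects,
            "standard_errors": self.standard_errors,
            "variance_components": self.variance_components,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_nests": self.n_nests,
            "n_cohorts": self.n_cohorts,
            "time_axis": self.time_axis,
            "converged": self.converged,
            "boundary": self.boundary,
            "trait": self.trait,
            "sex": self.sex,
            "A": self.A,
            "I": self.I,
        }


@dataclass
class ContrastResult:
    """Pairwise population differences in k with Wald t tests."""

    reference: str
    rows: pd.DataFrame  # columns: pop_a, pop_b, estimate, se, t, df, p


# ---------------------------------------------------------------------------
# fixed-effects (least squares) fit


def _prepare(records, trait, sex, time_axis):
    sub = records[records["sex"] == sex] if sex is not None else records
    t = _time_values(sub, time_axis)
    y = sub[trait].to_numpy(dtype=float)
    keep = (t > 0) & np.isfinite(y) & (y > 0)  # age-0 rows only inform I
    return sub.loc[keep], t[keep], y[keep]


def _ssr_derivs(y, t, A, c, k_per_obs):
    # clamp exponents so wild optimizer trial values degrade gracefully
    # instead of overflowing to nan
    g = c * np.exp(np.clip(-k_per_obs * t, None, 700.0))
    g = np.maximum(g, -700.0)
    f = A * np.exp(g)
    r = y - f
    fp = -t * g * f  # df/dk
    fpp = f * t * t * g * (1.0 + g)  # d2f/dk2
    return r, f, fp, fpp


def fit_fixed_gompertz(
    records: pd.DataFrame,
    trait: str,
    sex: str,
    A: float,
    I: float,
    time_axis: str = "age_days",
) -> FitResult:
    """Least-squares fit of k with A and I fixed, one sex at a time.

    Brent minimisation of the SSR followed by Newton polishing, so the
    optimum is located to machine precision (needed for exact axis-scaling
    identities).  Returns a flagged (converged=False) result rather than
    raising when the optimiser fails.
    """
    sub, t, y = _prepare(records, trait, sex, time_axis)
    if len(y) < 3:
        raise ValueError("need at least 3 positive-age records to fit k")
    c = np.log(I / A)

    def ssr(k):
        r = y - A * np.exp(c * np.exp(-k * t))
        return float(r @ r)

    t_scale = float(np.mean(t))
    k0 = np.log(np.log(A / I)) / t_scale if A / I > np.e else 1.0 / t_scale
    hi = max(10.0 / t_scale, 4 * abs(k0))
    res = optimize.minimize_scalar(ssr, bounds=(1e-12, hi), method="bounded",
                                   options={"xatol": 1e-14})
    k = float(res.x)
    converged = bool(res.success)
    for _ in range(8):  # Newton polish on dSSR/dk = 0
        r, f, fp, fpp = _ssr_derivs(y, t, A, c, k)
        grad = -2.0 * float(r @ fp)
        hess = 2.0 * float(fp @ fp - r @ fpp)
        if hess <= 0:
            break
        step = grad / hess
        if not np.isfinite(step):
            break
        k -= step
        if abs(step) < 1e-14 * max(abs(k), 1e-12):
            break
    r, f, fp, _ = _ssr_derivs(y, t, A, c, k)
    n = len(y)
    sigma2 = float(r @ r) / n
    # perfect (noise-free) fits give sigma2 = 0; keep loglik finite-safe
    loglik = -0.5 * n * (np.log(2 * np.pi * max(sigma2, 1e-300)) + 1.0)
    se_k = float(np.sqrt(sigma2 / (fp @ fp))) if fp @ fp > 0 else float("nan")
    return FitResult(
        fixed_effects={"k": k},
        standard_errors={"k": se_k},
        vcov=np.array([[se_k**2]]),
        variance_components={"sd_residual": float(np.sqrt(sigma2))},
        loglik=loglik,
        aic=-2 * loglik + 2 * 2,  # k and sigma
        n_obs=n,
        n_nests=sub["nest_id"].nunique(),
        n_cohorts=sub["cohort"].nunique(),
        time_axis=time_axis,
        converged=converged,
        trait=trait,
        sex=sex,
        A=A,
        I=I,
    )


# ---------------------------------------------------------------------------
# Laplace machinery for the nested random-effects model


class _LaplaceProblem:
    """Marginal likelihood of the Gompertz model with nested random effects.

    For fixed parameters theta = (beta, log sd_cohort, log sd_nest,
    log sd_resid) the joint penalised least-squares problem over the
    random-effect vector b (cohort effects then nest effects) is solved by
    damped Newton with the analytic gradient/Hessian, and the marginal
    log-likelihood follows from the Laplace approximation

        log L = -joint_nll(b_hat) + q/2 log(2 pi) - 1/2 log det H(b_hat).
    """

    def __init__(self, y, t, A, I, X, cohort_idx, nest_idx, n_cohorts, n_nests):
        self.y, self.t = y, t
        self.A, self.c = A, np.log(I / A)
        self.X = X  # n x p fixed-effects design (k_per_obs = X @ beta)
        self.ci = cohort_idx
        self.ni = n_cohorts + nest_idx  # offset into b
        self.nc, self.nn = n_cohorts, n_nests
        self.q = n_cohorts + n_nests
        self.n = len(y)
        self._b_warm = np.zeros(self.q)
        # nesting makes the joint Hessian block-diagonal by cohort:
        # effects from different cohorts never share an observation
        nest_cohort = np.zeros(n_nests, dtype=int)
        nest_cohort[nest_idx] = cohort_idx
        self.blocks = []
        for c_ in range(n_cohorts):
            nests_c = np.flatnonzero(nest_cohort == c_)
            local = {g: i + 1 for i, g in enumerate(nests_c)}
            obs = np.flatnonzero(cohort_idx == c_)
            local_rows = np.array([local[g] for g in nest_idx[obs]], dtype=int)
            gidx = np.concatenate(([c_], n_cohorts + nests_c))
            self.blocks.append((obs, local_rows, gidx))

    def _block_hessians(self, w, pen):
        """Assemble the per-cohort blocks of the joint Hessian."""
        out = []
        for obs, local_rows, gidx in self.blocks:
            s = len(gidx)
            Hb = np.zeros((s, s))
            wb = w[obs]
            Hb[0, 0] = wb.sum()
            np.add.at(Hb, (local_rows, local_rows), wb)
            np.add.at(Hb, (local_rows, np.zeros(len(obs), dtype=int)), wb)
            Hb[0, 1:] = Hb[1:, 0]
            Hb[np.diag_indices(s)] += pen[gidx]
            out.append(Hb)
        return out

    def _inner(self, beta, s2c, s2n, s2e):
        """Minimise the joint penalised objective over b by damped Newton."""
        y, t, A, c = self.y, self.t, self.A, self.c
        k_fix = self.X @ beta
        pen = np.concatenate(
            [np.full(self.nc, 1.0 / s2c), np.full(self.nn, 1.0 / s2n)]
        )
        b = self._b_warm.copy()

        def objective(bv):
            g = c * np.exp(np.clip(-(k_fix + bv[self.ci] + bv[self.ni]) * t, None, 700.0))
            r = y - A * np.exp(np.maximum(g, -700.0))
            return 0.5 * float(r @ r) / s2e + 0.5 * float(pen @ (bv * bv))

        obj = objective(b)
        for _ in range(60):
            ktot = k_fix + b[self.ci] + b[self.ni]
            r, f, fp, fpp = _ssr_derivs(y, t, A, c, ktot)
            gm = -(r * fp) / s2e
            grad = np.zeros(self.q)
            np.add.at(grad, self.ci, gm)
            np.add.at(grad, self.ni, gm)
            grad += pen * b
            if np.max(np.abs(grad)) < 1e-8 * max(1.0, obj):
                break
            w = (fp * fp - r * fpp) / s2e
            w_gn = (fp * fp) / s2e
            step = np.empty(self.q)
            for Hb, (obs, local_rows, gidx) in zip(
                self._block_hessians(w, pen), self.blocks
            ):
                gb = grad[gidx]
                try:
                    cf = linalg.cho_factor(Hb, check_finite=False)
                    step[gidx] = linalg.cho_solve(cf, gb, check_finite=False)
                except linalg.LinAlgError:
                    # indefinite away from the optimum: Gauss-Newton fallback,
                    # ridged if rounding makes it numerically semi-definite
                    s = len(gidx)
                    Hb = np.zeros((s, s))
                    wb = w_gn[obs]
                    Hb[0, 0] = wb.sum()
                    np.add.at(Hb, (local_rows, local_rows), wb)
                    np.add.at(Hb, (local_rows, np.zeros(len(obs), dtype=int)), wb)
                    Hb[0, 1:] = Hb[1:, 0]
                    Hb[np.diag_indices(s)] += pen[gidx]
                    scale = max(float(np.max(np.diag(Hb))), 1e-300)
                    ridge = 0.0
                    while True:
                        try:
                            cf = linalg.cho_factor(
                                Hb + ridge * scale * np.eye(s), check_finite=False
                            )
                            step[gidx] = linalg.cho_solve(
                                cf, gb, check_finite=False
                            )
                            break
                        except linalg.LinAlgError:
                            ridge = 1e-10 if ridge == 0.0 else ridge * 100.0
                            if ridge > 1.0:
                                step[gidx] = gb / np.diag(Hb)
                                break
            if np.max(np.abs(step)) < 1e-11 * (1.0 + np.max(np.abs(b))):
                break
            # backtracking line search; tiny non-decreases end the solve
            lam = 1.0
            accepted = False
            for _ls in range(12):
                b_new = b - lam * step
                obj_new = objective(b_new)
                if obj_new <= obj + 1e-12 * max(1.0, abs(obj)):
                    accepted = True
                    break
                lam *= 0.5
            if not accepted:
                break
            decrease = obj - obj_new
            b, obj = b_new, obj_new
            if decrease < 1e-11 * max(1.0, abs(obj)):
                break
        self._b_warm = b.copy()
        # exact Hessian blocks at the mode, for the Laplace log-determinant
        ktot = k_fix + b[self.ci] + b[self.ni]
        r, f, fp, fpp = _ssr_derivs(y, t, A, c, ktot)
        w = (fp * fp - r * fpp) / s2e
        return b, obj, self._block_hessians(w, pen), float(r @ r)

    def neg_marginal_loglik(self, theta: np.ndarray) -> float:
        p = self.X.shape[1]
        beta = theta[:p]
        s2c, s2n, s2e = np.exp(2.0 * theta[p:])
        b, obj, Hblocks, _rss = self._inner(beta, s2c, s2n, s2e)
        logdet = 0.0
        for Hb in Hblocks:
            sign, ld = np.linalg.slogdet(Hb)
            if sign <= 0:  # ridge the rare indefinite mode Hessian
                Hb = Hb + np.eye(len(Hb)) * 1e-8 * max(1.0, np.max(np.diag(Hb)))
                sign, ld = np.linalg.slogdet(Hb)
            logdet += ld
        const = (
            0.5 * self.n * np.log(2 * np.pi * s2e)
            + 0.5 * self.nc * np.log(2 * np.pi * s2c)
            + 0.5 * self.nn * np.log(2 * np.pi * s2n)
        )
        return obj + const - 0.5 * self.q * np.log(2 * np.pi) + 0.5 * logdet


def _numeric_hessian(fun, x, steps):
    p = len(x)
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            hi, hj = steps[i], steps[j]
            if i == j:
                f0 = fun(x)
                fp = fun(x + 2 * hi * _unit(p, i))
                fm = fun(x - 2 * hi * _unit(p, i))
                H[i, i] = (fp - 2 * f0 + fm) / (4 * hi * hi)
            else:
                ei, ej = _unit(p, i) * hi, _unit(p, j) * hj
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * hi * hj)
    return H


def _unit(p, i):
    e = np.zeros(p)
    e[i] = 1.0
    return e


def _laplace_fit(
    records, trait, sex, A, I, time_axis, X_builder, beta_names, compute_se
):
    sub, t, y = _prepare(records, trait, sex, time_axis)
    if sub["cohort"].nunique() < 2:
        raise ValueError("need >=2 cohorts for the nested random-effects model")
    # a cohort is a colony-year: the same calendar year in two colonies is
    # two distinct rearing environments
    cohort_key = sub["population"].astype(str) + ":" + sub["cohort"].astype(str)
    cohort_codes, _ = pd.factorize(cohort_key)
    nest_codes, _ = pd.factorize(sub["nest_id"])
    nc, nn = cohort_codes.max() + 1, nest_codes.max() + 1
    X = X_builder(sub)
    prob = _LaplaceProblem(y, t, A, I, X, cohort_codes, nest_codes, nc, nn)
    p = X.shape[1]

    # starting values from the fixed fit
    start = fit_fixed_gompertz(sub.assign(), trait, sex, A, I, time_axis)
    k0 = start.k
    sde0 = start.variance_components["sd_residual"]
    beta0 = np.zeros(p)
    beta0[0] = k0
    theta0 = np.concatenate(
        [beta0, np.log([max(0.1 * k0, 1e-6), max(0.1 * k0, 1e-6), sde0])]
    )
    bounds = [(1e-8, None)] + [(None, None)] * (p - 1)
    bounds += [(-12.0, 6.0), (-12.0, 6.0), (np.log(sde0) - 6.0, np.log(sde0) + 4.0)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            prob.neg_marginal_loglik,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-8},
        )
    theta = res.x
    loglik = -float(res.fun)
    beta = theta[:p]
    sds = np.exp(theta[p:])
    boundary = [
        name
        for name, logsd in zip(["sd_cohort", "sd_nest"], theta[p : p + 2])
        if logsd <= LOG_SD_FLOOR
    ]

    ses = {name: float("nan") for name in beta_names}
    vcov = None
    if compute_se:
        steps = np.concatenate(
            [np.maximum(1e-4 * np.abs(beta), 1e-7), np.full(3, 1e-3)]
        )
        Hm = _numeric_hessian(prob.neg_marginal_loglik, theta, steps)
        try:
            vcov_full = np.linalg.inv(Hm)
            diag = np.diag(vcov_full)
            if np.any(diag[:p] <= 0):
                raise np.linalg.LinAlgError
            vcov = vcov_full
            for i, name in enumerate(beta_names):
                ses[name] = float(np.sqrt(diag[i]))
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular information matrix; standard errors unavailable",
                stacklevel=2,
            )
            vcov = None

    n_params = p + 3
    return (
        FitResult(
            fixed_effects=dict(zip(beta_names, map(float, beta))),
            standard_errors=ses,
            vcov=vcov,
            variance_components={
                "sd_cohort": float(sds[0]),
                "sd_nest": float(sds[1]),
                "sd_residual": float(sds[2]),
            },
            loglik=loglik,
            aic=-2 * loglik + 2 * n_params,
            n_obs=len(y),
            n_nests=int(nn),
            n_cohorts=int(nc),
            time_axis=time_axis,
            converged=bool(res.success),
            boundary=boundary,
            trait=trait,
            sex=sex,
            A=A,
            I=I,
        ),
        sub,
    )


def marginal_loglik(
    records: pd.DataFrame,
    trait: str,
    sex: str,
    A: float,
    I: float,
    k: float,
    sd_cohort: float,
    sd_nest: float,
    sd_residual: float,
    time_axis: str = "age_days",
) -> float:
    """Laplace marginal log-likelihood at given parameter values."""
    sub, t, y = _prepare(records, trait, sex, time_axis)
    cohort_key = sub["population"].astype(str) + ":" + sub["cohort"].astype(str)
    cohort_codes, _ = pd.factorize(cohort_key)
    nest_codes, _ = pd.factorize(sub["nest_id"])
    prob = _LaplaceProblem(
        y, t, A, I, np.ones((len(sub), 1)), cohort_codes, nest_codes,
        cohort_codes.max() + 1, nest_codes.max() + 1,
    )
    theta = np.array([k, *np.log([sd_cohort, sd_nest, sd_residual])])
    return -prob.neg_marginal_loglik(theta)


def fit_random_gompertz(
    records: pd.DataFrame,
    trait: str,
    sex: str,
    A: float,
    I: float,
    time_axis: str = "age_days",
    compute_se: bool = True,
) -> FitResult:
    """Maximum-likelihood fit of the nested random-effects Gompertz model.

    Cohort and nest-within-cohort effects on k are Gaussian with mean zero;
    they are integrated out with a Laplace approximation whose inner mode
    is found by damped Newton.  Standard errors come from the numerical
    Hessian of the marginal log-likelihood (set ``compute_se=False`` to
    skip them in large simulation loops).
    """
    result, _ = _laplace_fit(
        records,
        trait,
        sex,
        A,
        I,
        time_axis,
        X_builder=lambda sub: np.ones((len(sub), 1)),
        beta_names=["k"],
        compute_se=compute_se,
    )
    return result


def fit_population_contrast(
    records: pd.DataFrame,
    trait: str,
    sex: str,
    A: float,
    I: float,
    time_axis: str = "age_days",
    reference: str = "barents",
    compute_se: bool = True,
) -> tuple[FitResult, ContrastResult]:
    """Joint multi-population model with treatment-coded offsets on k.

    The reference population's k is the baseline; each other population
    gets a dummy-coded difference ``k_<pop>``.  Wald t statistics use
    df = n_nests − n_fixed_effects.  Populations absent from the data are
    dropped with a warning.
    """
    pops = [p for p in records["population"].unique()]
    if reference not in pops:
        raise ValueError(f"reference population {reference!r} not in data")
    others = sorted(p for p in pops if p != reference)
    if not others:
        raise ValueError("need records from >=2 populations")
    beta_names = ["k"] + [f"k_{p}" for p in others]

    def build_X(sub):
        X = np.ones((len(sub), 1 + len(others)))
        for j, p_ in enumerate(others, start=1):
            X[:, j] = (sub["population"] == p_).to_numpy(dtype=float)
        return X

    result, sub = _laplace_fit(
        records, trait, sex, A, I, time_axis, build_X, beta_names, compute_se
    )
    df_t = result.n_nests - len(beta_names)
    rows = []
    p_fe = len(beta_names)
    V = result.vcov[:p_fe, :p_fe] if result.vcov is not None else None

    def wald(est, var):
        se = float(np.sqrt(var)) if var is not None and var > 0 else float("nan")
        tstat = est / se if np.isfinite(se) and se > 0 else float("nan")
        pval = (
            2 * stats.t.sf(abs(tstat), df_t) if np.isfinite(tstat) else float("nan")
        )
        return se, tstat, pval

    for j, p_ in enumerate(others, start=1):
        est = result.fixed_effects[f"k_{p_}"]
        var = V[j, j] if V is not None else None
        se, tstat, pval = wald(est, var)
        rows.append((p_, reference, est, se, tstat, df_t, pval))
    # pairwise among non-reference populations
    for ia in range(len(others)):
        for ib in range(ia + 1, len(others)):
            pa, pb = others[ia], others[ib]
            est = result.fixed_effects[f"k_{pa}"] - result.fixed_effects[f"k_{pb}"]
            var = (
                V[ia + 1, ia + 1] + V[ib + 1, ib + 1] - 2 * V[ia + 1, ib + 1]
                if V is not None
                else None
            )
            se, tstat, pval = wald(est, var)
            rows.append((pa, pb, est, se, tstat, df_t, pval))
    table = pd.DataFrame(
        rows, columns=["pop_a", "pop_b", "estimate", "se", "t", "df", "p"]
    )
    return result, ContrastResult(reference=reference, rows=table)
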
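"""Hatch-date and trend analyses on growth-curve residuals.

Residuals are observed minus predicted size from the fixed-effects-only
(sex-specific) Gompertz fits.  They are modelled with Gaussian linear
mixed models: fixed effects for population, relative hatch date (days
from the colony's cohort mean), their interaction and sex, and random
intercepts for cohort and for nest nested within cohort.  Backward AIC
selection drops terms that do not improve the fit, respecting
marginality (the interaction is removed before its main effects).

Model fitting is delegated to statsmodels MixedLM with ML (not REML) so
AIC values are comparable across fixed-effect structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .growth import FitResult

__all__ = [
    "compute_residuals",
    "relative_hatch_date",
    "fit_residual_lmm",
    "hatch_slopes",
    "backward_aic_select",
    "annual_trend",
    "LmmSummary",
]

FULL_TERMS = ("population", "rel_hatch_date", "population:rel_hatch_date", "sex")


def compute_residuals(
    records: pd.DataFrame,
    fixed_fit_by_sex: dict[str, FitResult],
    trait: str,
    time_axis: str = "age_days",
) -> pd.DataFrame:
    """Observed minus Gompertz-predicted size, sexes pooled afterwards.

    A fixed-effects fit must be supplied for every sex present.
    """
    present = set(records["sex"].unique())
    missing = present - set(fixed_fit_by_sex)
    if missing:
        raise ValueError(f"no fitted model for sex(es): {sorted(missing)}")
    out = records.copy()
    if time_axis == "age_days":
        t = out["age_days"].to_numpy(dtype=float)
    else:
        t = out["daylight_h"].to_numpy(dtype=float)
    pred = np.empty(len(out))
    for sex, fit in fixed_fit_by_sex.items():
        mask = (out["sex"] == sex).to_numpy()
        pred[mask] = fit.predict(t[mask])
    out["residual"] = out[trait].to_numpy(dtype=float) - pred
    return out


def relative_hatch_date(
    records: pd.DataFrame,
    colony_cohort_means: dict[tuple[str, int], float] | None = None,
) -> pd.DataFrame:
    """Attach relative hatch dates (days from the colony's cohort mean).

    ``colony_cohort_means`` maps (population, cohort) to a mean hatch
    day-of-year, as established from full-colony nest monitoring.  If
    omitted, means are computed from the data themselves.
    """
    out = records.copy()
    doy = np.array([d.timetuple().tm_yday for d in out["hatch_date"]], dtype=float)
    out["hatch_doy"] = doy
    if colony_cohort_means is None:
        means = out.groupby(["population", "cohort"])["hatch_doy"].transform("mean")
        out["rel_hatch_date"] = doy - means.to_numpy()
    else:
        keys = list(zip(out["population"], out["cohort"]))
        missing = {k for k in keys if k not in colony_cohort_means}
        if missing:
            raise ValueError(f"missing cohort mean hatch date for: {sorted(missing)}")
        out["rel_hatch_date"] = doy - np.array(
            [colony_cohort_means[k] for k in keys]
        )
    return out


@dataclass
class LmmSummary:
    """Fixed-effect table, variance components, AIC and marginal F tests."""

    terms: tuple[str, ...]
    formula: str
    params: pd.Series
    bse: pd.Series
    cov_fe: pd.DataFrame
    variance_components: dict[str, float]
    loglik: float
    aic: float
    n_obs: int
    n_groups: int
    f_tests: pd.DataFrame  # term, F, df_num, df_den, p
    converged: bool


def _formula(terms) -> str:
    parts = []
    for term in terms:
        if term == "population":
            parts.append("C(population)")
        elif term == "sex":
            parts.append("C(sex)")
        elif term == "rel_hatch_date":
            parts.append("rel_hatch_date")
        elif term == "population:rel_hatch_date":
            parts.append("C(population):rel_hatch_date")
        else:
            raise ValueError(f"unknown term {term!r}")
    rhs = " + ".join(parts) if parts else "1"
    return f"residual ~ {rhs}"


def _fit_mixedlm(formula: str, df: pd.DataFrame, use_nest: bool = True):
    data = df.copy()
    data["cohort_id"] = (
        data["population"].astype(str) + ":" + data["cohort"].astype(str)
    )
    vc = {"nest": "0 + C(nest_id)"} if use_nest else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            formula, data, groups="cohort_id", re_formula="1", vc_formula=vc
        )
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=400)
        except Exception:
            res = model.fit(reml=False, method="powell", maxiter=800)
    return model, res


def fit_residual_lmm(
    residuals: pd.DataFrame,
    terms: tuple[str, ...] = FULL_TERMS,
) -> LmmSummary:
    """Gaussian LMM of residual size with nested random intercepts.

    ``terms`` selects the fixed effects from {population, rel_hatch_date,
    population:rel_hatch_date, sex}.  The interaction requires >=2
    populations.  Marginal (Type-III-style) Wald F tests are reported per
    term with containment denominator df = n_nests − rank(X).  If the
    nested nest component is singular (zero variance) the model is refit
    without it, with a warning.
    """
    if "population:rel_hatch_date" in terms:
        if residuals["population"].nunique() < 2:
            raise ValueError("interaction model needs >=2 populations")
        needed = {"population", "rel_hatch_date"}
        if not needed <= set(terms):
            raise ValueError("interaction requires both main effects (marginality)")
    formula = _formula(terms)
    model, res = _fit_mixedlm(formula, residuals)
    vc_nest = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    if len(res.vcomp) and (not np.isfinite(vc_nest) or vc_nest < 1e-12):
        warnings.warn("nest variance component at boundary; refitting without it",
                      stacklevel=2)
        model, res = _fit_mixedlm(formula, residuals, use_nest=False)

    k_fe = model.k_fe
    params = res.params[:k_fe]
    bse = res.bse[:k_fe]
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[:k_fe, :k_fe],
        index=params.index,
        columns=params.index,
    )
    vcomp = {"var_cohort": float(res.cov_re.iloc[0, 0]),
             "var_residual": float(res.scale)}
    if len(res.vcomp):
        vcomp["var_nest"] = float(res.vcomp[0])
    n_nests = residuals["nest_id"].nunique()
    df_den = max(n_nests - k_fe, 1)

    design_info = model.data.design_info
    frows = []
    beta = params.to_numpy()
    V = cov.to_numpy()
    for term in design_info.terms:
        name = term.name()
        if name == "Intercept":
            continue
        sl = design_info.term_name_slices[name]
        idx = np.arange(k_fe)[sl]
        L = np.zeros((len(idx), k_fe))
        L[np.arange(len(idx)), idx] = 1.0
        est = L @ beta
        try:
            fstat = float(est @ np.linalg.solve(L @ V @ L.T, est)) / len(idx)
        except np.linalg.LinAlgError:
            fstat = float("nan")
        pval = float(stats.f.sf(fstat, len(idx), df_den))
        frows.append((name, fstat, len(idx), df_den, pval))
    f_tests = pd.DataFrame(frows, columns=["term", "F", "df_num", "df_den", "p"])

    n_params = k_fe + 1 + len(res.vcomp) + 1  # fe + cohort var + vc + resid var
    loglik = float(res.llf)
    return LmmSummary(
        terms=tuple(terms),
        formula=formula,
        params=params,
        bse=bse,
        cov_fe=cov,
        variance_components=vcomp,
        loglik=loglik,
        aic=-2 * loglik + 2 * n_params,
        n_obs=len(residuals),
        n_groups=residuals["nest_id"].nunique(),
        f_tests=f_tests,
        converged=bool(res.converged),
    )


def hatch_slopes(summary: LmmSummary, populations: list[str]) -> pd.DataFrame:
    """Per-population hatch-date slope with SE and 95% CI.

    Under treatment coding the reference population's slope is the
    ``rel_hatch_date`` coefficient; other populations add their
    interaction term.
    """
    names = list(summary.params.index)
    if "rel_hatch_date" not in names:
        raise ValueError("model contains no hatch-date slope")
    base_i = names.index("rel_hatch_date")
    beta = summary.params.to_numpy()
    V = summary.cov_fe.to_numpy()
    ref = sorted(populations)[0]
    rows = []
    for pop in sorted(populations):
        vec = np.zeros(len(beta))
        vec[base_i] = 1.0
        if pop != ref:
            iname = f"C(population)[T.{pop}]:rel_hatch_date"
            if iname in names:
                vec[names.index(iname)] = 1.0
        slope = float(vec @ beta)
        se = float(np.sqrt(vec @ V @ vec))
        rows.append((pop, slope, se, slope - 1.96 * se, slope + 1.96 * se))
    return pd.DataFrame(rows, columns=["population", "slope", "se", "lo95", "hi95"])


def population_hatch_slopes(residuals: pd.DataFrame) -> pd.DataFrame:
    """Hatch-date slope per population from colony-specific mixed models.

    Variance components (nest, cohort, residual) differ strongly between
    colonies because capture-age ranges differ, so a pooled model's
    common variance misstates per-colony slope uncertainty; each colony
    is therefore fit on its own (``residual ~ rel_hatch_date + sex`` with
    the nested random intercepts).  The pooled interaction model remains
    the instrument for testing whether slopes differ between colonies.
    """
    rows = []
    for pop, sub in residuals.groupby("population"):
        terms = ("rel_hatch_date", "sex") if sub["sex"].nunique() > 1 else (
            "rel_hatch_date",
        )
        summ = fit_residual_lmm(sub, terms)
        i = list(summ.params.index).index("rel_hatch_date")
        slope, se = float(summ.params.iloc[i]), float(summ.bse.iloc[i])
        rows.append((pop, slope, se, slope - 1.96 * se, slope + 1.96 * se))
    return pd.DataFrame(rows, columns=["population", "slope", "se", "lo95", "hi95"])


def backward_aic_select(
    residuals: pd.DataFrame,
    full_terms: tuple[str, ...] = FULL_TERMS,
) -> tuple[LmmSummary, pd.DataFrame]:
    """Backward AIC selection from the full fixed-effect structure.

    At each step the removable term whose removal lowers AIC most is
    dropped (the interaction is removable before its main effects);
    selection stops when no removal lowers AIC.  Returns the selected
    model and the full AIC trace.
    """
    def _n_params(f: LmmSummary) -> int:
        return len(f.params) + len(f.variance_components)

    current = tuple(full_terms)
    fit = fit_residual_lmm(residuals, current)
    trace = [
        {"terms": " + ".join(current) or "1", "aic": fit.aic,
         "loglik": fit.loglik, "n_params": _n_params(fit), "action": "full"}
    ]
    while True:
        candidates = []
        for term in current:
            if term in ("population", "rel_hatch_date") and (
                "population:rel_hatch_date" in current
            ):
                continue  # marginality: interaction goes first
            candidates.append(term)
        best = None
        for term in candidates:
            reduced = tuple(t for t in current if t != term)
            f = fit_residual_lmm(residuals, reduced)
            if best is None or f.aic < best[1].aic:
                best = (term, f, reduced)
        if best is None or best[1].aic >= fit.aic:
            break
        current, fit = best[2], best[1]
        trace.append(
            {"terms": " + ".join(current) or "1", "aic": fit.aic,
             "loglik": fit.loglik, "n_params": _n_params(fit),
             "action": f"dropped {best[0]}"}
        )
    return fit, pd.DataFrame(trace)


def annual_trend(residuals: pd.DataFrame) -> dict[str, float]:
    """Across-year trend of residual size, in trait units per year.

    Linear mixed regression of the residual on cohort year with random
    nest intercepts.  Requires >=3 distinct cohorts.
    """
    if residuals["cohort"].nunique() < 3:
        raise ValueError("need >=3 cohorts to estimate an annual trend")
    data = residuals.copy()
    data["year_c"] = data["cohort"].astype(float) - data["cohort"].astype(float).mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            "residual ~ year_c", data, groups="nest_id", re_formula="1"
        )
        res = model.fit(reml=False, method="lbfgs", maxiter=400)
    slope = float(res.params["year_c"])
    se = float(res.bse["year_c"])
    return {
        "slope_per_year": slope,
        "se": se,
        "lo95": slope - 1.96 * se,
        "hi95": slope + 1.96 * se,
        "n_obs": int(len(data)),
        "n_years": int(data["cohort"].nunique()),
    }
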
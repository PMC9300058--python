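"""Synthetic cross-sectional gosling biometrics.

Emulates the sampling structure of colony ringing studies: goslings are
clustered in nests (broods) within annual cohorts, every gosling is
measured exactly once at a capture age drawn from a colony-specific
distribution, and each trait follows a fixed-endpoint Gompertz curve with
Gaussian random effects on the growth coefficient at the cohort and nest
level, an additive relative-hatch-date effect, a Gaussian measurement
residual, and instrument rounding.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .daylight import accumulated_daylight
from .growth import gompertz_size
from .scenarios import (
    HEAD_GRID_MM,
    MASS_GRID_COARSE_G,
    MASS_GRID_FINE_G,
    MASS_SPLIT_G,
    TARSUS_GRID_MM,
    SEXES,
    ScenarioConfig,
    ScenarioError,
)

CSV_COLUMNS = [
    "gosling_id",
    "population",
    "sex",
    "cohort",
    "nest_id",
    "hatch_date",
    "capture_date",
    "age_days",
    "mass_g",
    "head_mm",
    "tarsus_mm",
]


def _round_to_grid(value: np.ndarray, grid: float) -> np.ndarray:
    # round half away from zero on the instrument grid
    return np.floor(np.abs(value) / grid + 0.5) * grid * np.sign(value)


def apply_measurement_rounding(trait: str, value):
    """Round a raw measurement onto the field instrument's grid.

    Spring/hand scales: nearest 5 g below 600 g, nearest 10 g above;
    calliper (tarsus): 0.1 mm; ruler (head): 1 mm.
    """
    value = np.asarray(value, dtype=float)
    if np.any(value <= 0):
        raise ValueError("measurements must be positive")
    if trait == "mass_g":
        fine = _round_to_grid(value, MASS_GRID_FINE_G)
        coarse = _round_to_grid(value, MASS_GRID_COARSE_G)
        out = np.where(value < MASS_SPLIT_G, fine, coarse)
        out = np.maximum(out, MASS_GRID_FINE_G)
    elif trait == "tarsus_mm":
        out = np.round(_round_to_grid(value, TARSUS_GRID_MM), 1)
        out = np.maximum(out, TARSUS_GRID_MM)
    elif trait == "head_mm":
        out = np.maximum(_round_to_grid(value, HEAD_GRID_MM), HEAD_GRID_MM)
    else:
        raise ValueError(f"unknown trait {trait!r}")
    return out if out.shape else float(out)


def _triangular_mode(a: float, m: float, b: float) -> float:
    """Mode of a triangular distribution on [a, b] whose median is m."""
    if a == b:
        return a
    # median below mode: F(m) = (m-a)^2 / ((b-a)(c-a)) = 1/2
    c = a + 2.0 * (m - a) ** 2 / (b - a)
    if c < m:  # median above mode instead
        c = b - 2.0 * (b - m) ** 2 / (b - a)
    return min(max(c, a), b)


def sample_capture_ages(
    config: ScenarioConfig, n: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Integer capture ages from a discretised triangular distribution.

    The triangle's mode is placed so the continuous median equals the
    configured median; draws are rounded to whole days and truncated to
    [capture_age_min, capture_age_max].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng() if rng is None else rng
    a, m, b = config.capture_age_min, config.capture_age_median, config.capture_age_max
    if a == b:
        return np.full(n, a, dtype=int)
    c = _triangular_mode(float(a), float(m), float(b))
    draws = rng.triangular(a, c, b, size=n)
    return np.clip(np.rint(draws).astype(int), a, b)


def generate_scenario(
    config: ScenarioConfig,
    seed: int | None = None,
    growth_clock: str = "age",
    scale: float = 1.0,
    round_measurements: bool = True,
) -> pd.DataFrame:
    """Generate one cross-sectional dataset for a colony scenario.

    Parameters
    ----------
    config
        Colony scenario; its variance fields must be non-negative and
        every trait must satisfy 0 < I < A (enforced on construction).
    seed
        Overrides ``config.seed``.  Identical config+seed gives
        byte-identical output.
    growth_clock
        ``"age"``: sizes follow the Gompertz curve in ``true_k`` units of
        days since hatch.  ``"daylight"``: sizes follow ``true_k_daylight``
        in units of accumulated dawn-to-dusk hours, with random-effect SDs
        rescaled by the per-sex ratio ``true_k_daylight/true_k``.
    scale
        Multiplies nests per cohort, for reduced-size runs (min 2 nests).

    Returns a DataFrame with exactly the external CSV columns.
    """
    if growth_clock not in ("age", "daylight"):
        raise ScenarioError(f"unknown growth clock {growth_clock!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    traits = config.traits
    n_nests = max(2, int(round(config.nests_per_cohort * scale)))

    rows: list[dict] = []
    for ci in range(config.n_cohorts):
        year = config.first_year + ci
        cohort_mean_doy = config.mean_hatch_doy + rng.normal(
            0.0, config.cohort_mean_sd_days
        )
        k_cohort = {t: rng.normal(0.0, s.sd_cohort) for t, s in traits.items()}
        for ni in range(n_nests):
            nest_id = f"{config.population[:3].upper()}-{year}-N{ni + 1:03d}"
            hatch_doy = int(round(rng.normal(cohort_mean_doy, config.hatch_sd_days)))
            hatch_doy = max(1, min(hatch_doy, 330))
            hatch_date = dt.date(year, 1, 1) + dt.timedelta(days=hatch_doy - 1)
            rel_hatch = hatch_doy - cohort_mean_doy
            k_nest = {t: rng.normal(0.0, s.sd_nest) for t, s in traits.items()}
            brood = 1 + rng.poisson(config.brood_size_mean - 1.0)
            for gi in range(brood):
                sex = SEXES[int(rng.integers(0, 2))]
                age = int(sample_capture_ages(config, 1, rng)[0])
                capture_date = hatch_date + dt.timedelta(days=age)
                if growth_clock == "age":
                    t_grow = float(age)
                else:
                    t_grow = accumulated_daylight(
                        config.latitude_deg, config.longitude_deg,
                        hatch_date, capture_date,
                    )
                row = {
                    "gosling_id": f"{nest_id}-G{gi + 1}",
                    "population": config.population,
                    "sex": sex,
                    "cohort": year,
                    "nest_id": nest_id,
                    "hatch_date": hatch_date,
                    "capture_date": capture_date,
                    "age_days": age,
                }
                for trait, spec in traits.items():
                    k_true = spec.true_k[sex]
                    if growth_clock == "age":
                        k_base, ratio = k_true, 1.0
                    else:
                        k_base = spec.true_k_daylight[sex]
                        ratio = k_base / k_true
                    k_tot = k_base + ratio * (k_cohort[trait] + k_nest[trait])
                    mean = gompertz_size(
                        spec.adult_A[sex], spec.hatch_I, max(k_tot, 1e-8), t_grow
                    )
                    mean += spec.hatchdate_slope * rel_hatch
                    mean += config.annual_trend.get(trait, 0.0) * ci
                    raw = mean + rng.normal(0.0, spec.sd_residual)
                    while raw <= 0:  # sizes are physical, redraw the rare negative
                        raw = mean + rng.normal(0.0, spec.sd_residual)
                    row[trait] = (
                        apply_measurement_rounding(trait, raw)
                        if round_measurements
                        else raw
                    )
                rows.append(row)
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return df
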
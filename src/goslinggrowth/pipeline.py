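"""End-to-end analysis pipeline: simulate → fit → contrast → residuals → haldanes.

Mirrors the full colony comparison: three simulated colonies, nested
random-effects Gompertz fits for every population × sex × trait on both
the age and the accumulated-daylight axis (36 fits), joint population
contrasts, the hatch-date residual analysis with backward AIC selection,
the Baltic across-year trend, and haldane rates between the Arctic and
sedentary populations.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .growth import (
    attach_time_axis,
    fit_fixed_gompertz,
    fit_population_contrast,
    fit_random_gompertz,
)
from .rates import generations, haldane
from .residuals import (
    annual_trend,
    backward_aic_select,
    compute_residuals,
    hatch_slopes,
    population_hatch_slopes,
    relative_hatch_date,
)
from .scenarios import SEXES, TRAITS, ScenarioConfig, load_all_presets
from .synthetic import generate_scenario

GENERATION_TIME_YEARS = 7.5
PERIOD_YEARS = 30.0


def _substream_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def config_hash(configs: dict[str, ScenarioConfig]) -> str:
    blob = yaml.safe_dump({k: v.to_dict() for k, v in sorted(configs.items())})
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_full_pipeline(
    seed: int,
    configs: dict[str, ScenarioConfig] | None = None,
    scale: float = 1.0,
    out_dir: str | Path | None = None,
    compute_se: bool = True,
) -> dict:
    """Run the whole analysis on freshly simulated colony data.

    Returns a JSON-serialisable report bundle carrying the seed, a config
    hash and per-stage wall times.  ``scale`` shrinks the number of nests
    per cohort for quick runs.  Any stage failure raises with the stage
    name attached.
    """
    configs = configs or load_all_presets()
    pops = sorted(configs)
    coords = {
        p: (configs[p].latitude_deg, configs[p].longitude_deg) for p in pops
    }
    seeds = dict(zip(pops, _substream_seeds(seed, len(pops))))
    report: dict = {
        "tool_version": __version__,
        "seed": seed,
        "config_hash": config_hash(configs),
        "scale": scale,
        "stage_seconds": {},
    }
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        data = {
            p: generate_scenario(configs[p], seed=seeds[p], scale=scale)
            for p in pops
        }
        pooled = pd.concat(data.values(), ignore_index=True)
        pooled_dl = attach_time_axis(pooled, "daylight_hours", coords)
        report["n_records"] = {p: int(len(d)) for p, d in data.items()}
        report["stage_seconds"][stage] = round(time.perf_counter() - t0, 2)

        stage = "fit"
        t0 = time.perf_counter()
        fits: dict[str, dict] = {}
        for pop in pops:
            cfg = configs[pop]
            for trait in TRAITS:
                spec = cfg.trait(trait)
                for sex in SEXES:
                    for axis, frame in (
                        ("age_days", pooled),
                        ("daylight_hours", pooled_dl),
                    ):
                        sub = frame[frame["population"] == pop]
                        fit = fit_random_gompertz(
                            sub, trait, sex, spec.adult_A[sex], spec.hatch_I,
                            time_axis=axis, compute_se=compute_se,
                        )
                        fits[f"{pop}.{trait}.{sex}.{axis}"] = fit.to_dict()
        report["fits"] = fits
        report["stage_seconds"][stage] = round(time.perf_counter() - t0, 2)

        stage = "contrast"
        t0 = time.perf_counter()
        contrasts = {}
        ref = "barents" if "barents" in pops else pops[0]
        any_cfg = configs[pops[0]]
        for trait in TRAITS:
            spec = any_cfg.trait(trait)
            for sex in SEXES:
                for axis, frame in (
                    ("age_days", pooled),
                    ("daylight_hours", pooled_dl),
                ):
                    _, contrast = fit_population_contrast(
                        frame, trait, sex, spec.adult_A[sex], spec.hatch_I,
                        time_axis=axis, reference=ref, compute_se=compute_se,
                    )
                    contrasts[f"{trait}.{sex}.{axis}"] = contrast.rows.to_dict(
                        "records"
                    )
        report["contrasts"] = contrasts
        report["stage_seconds"][stage] = round(time.perf_counter() - t0, 2)

        stage = "residuals"
        t0 = time.perf_counter()
        resid_out = {}
        for trait in TRAITS:
            spec = any_cfg.trait(trait)
            fit_by_sex = {
                sex: fit_fixed_gompertz(
                    pooled, trait, sex, spec.adult_A[sex], spec.hatch_I
                )
                for sex in SEXES
            }
            resid = compute_residuals(pooled, fit_by_sex, trait)
            resid = relative_hatch_date(resid)
            selected, trace = backward_aic_select(resid)
            entry = {
                "selected_terms": list(selected.terms),
                "aic_trace": trace.to_dict("records"),
                "f_tests": selected.f_tests.to_dict("records"),
            }
            if "rel_hatch_date" in selected.terms:
                entry["hatch_slopes_pooled_model"] = hatch_slopes(
                    selected, pops
                ).to_dict("records")
            entry["hatch_slopes_by_colony"] = population_hatch_slopes(
                resid
            ).to_dict("records")
            if trait == "mass_g" and "baltic" in pops:
                baltic_resid = resid[resid["population"] == "baltic"]
                if baltic_resid["cohort"].nunique() >= 3:
                    entry["baltic_annual_trend"] = annual_trend(baltic_resid)
            resid_out[trait] = entry
        report["residual_analysis"] = resid_out
        report["stage_seconds"][stage] = round(time.perf_counter() - t0, 2)

        stage = "haldane"
        t0 = time.perf_counter()
        g = generations(PERIOD_YEARS, GENERATION_TIME_YEARS)
        haldanes = []
        if {"barents", "northsea"} <= set(pops):
            for trait in TRAITS:
                for sex in SEXES:
                    fb = fits[f"barents.{trait}.{sex}.age_days"]
                    fn = fits[f"northsea.{trait}.{sex}.age_days"]

                    def _between_sd(f):
                        vc = f["variance_components"]
                        return vc["sd_cohort"] ** 2 + vc["sd_nest"] ** 2

                    sp = float(np.sqrt(0.5 * (_between_sd(fb) + _between_sd(fn))))
                    if sp <= 0:
                        continue
                    haldanes.append(
                        {
                            "trait": trait,
                            "sex": sex,
                            "X1_northsea": fn["fixed_effects"]["k"],
                            "X2_barents": fb["fixed_effects"]["k"],
                            "Sp": sp,
                            "g": g,
                            "h": haldane(
                                fn["fixed_effects"]["k"],
                                fb["fixed_effects"]["k"],
                                sp,
                                g,
                            ),
                        }
                    )
        report["haldanes"] = haldanes
        report["stage_seconds"][stage] = round(time.perf_counter() - t0, 2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        for p, d in data.items():
            from .io import write_gosling_csv

            write_gosling_csv(d, out / f"{p}.csv")
    return report
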
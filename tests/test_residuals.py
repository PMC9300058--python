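import numpy as np
import pandas as pd
import pytest

from goslinggrowth.growth import fit_fixed_gompertz
from goslinggrowth.residuals import (
    annual_trend,
    backward_aic_select,
    compute_residuals,
    fit_residual_lmm,
    hatch_slopes,
    relative_hatch_date,
)
from goslinggrowth.synthetic import generate_scenario

from conftest import noise_free, with_trait
from _oracles import gls_coefficients


def _mass_fits(df, cfg):
    spec = cfg.trait("mass_g")
    return {
        s: fit_fixed_gompertz(df, "mass_g", s, spec.adult_A[s], spec.hatch_I)
        for s in ("male", "female")
    }


class TestComputeResiduals:
    def test_exact_curve_gives_zero_residuals(self, barents_noise_free):
        df = generate_scenario(barents_noise_free, seed=40, round_measurements=False)
        resid = compute_residuals(df, _mass_fits(df, barents_noise_free), "mass_g")
        np.testing.assert_allclose(resid["residual"], 0.0, atol=1e-6)

    def test_mean_residual_near_zero(self, presets):
        df = generate_scenario(presets["baltic"], seed=41, scale=0.5)
        resid = compute_residuals(df, _mass_fits(df, presets["baltic"]), "mass_g")
        sd = resid["residual"].std()
        # least-squares property, weakened by the shared-sex pooling
        assert abs(resid["residual"].mean()) < 0.2 * sd

    def test_offset_translates_residual(self, barents_noise_free):
        df = generate_scenario(barents_noise_free, seed=42, round_measurements=False)
        fits = _mass_fits(df, barents_noise_free)
        df.loc[df.index[0], "mass_g"] += 50.0
        resid = compute_residuals(df, fits, "mass_g")
        assert resid["residual"].iloc[0] == pytest.approx(50.0, abs=1e-6)
        assert abs(resid["residual"].iloc[1:]).max() < 1e-6

    def test_missing_sex_fit_rejected(self, presets):
        df = generate_scenario(presets["northsea"], seed=43, scale=0.3)
        fits = _mass_fits(df, presets["northsea"])
        fits.pop("female")
        with pytest.raises(ValueError):
            compute_residuals(df, fits, "mass_g")


class TestRelativeHatchDate:
    def test_known_means(self):
        import datetime as dt

        df = pd.DataFrame(
            {
                "population": ["barents"] * 2,
                "cohort": [2003, 2003],
                "hatch_date": [dt.date(2003, 7, 10), dt.date(2003, 7, 15)],
            }
        )
        means = {("barents", 2003): dt.date(2003, 7, 10).timetuple().tm_yday}
        out = relative_hatch_date(df, means)
        assert out["rel_hatch_date"].tolist() == [0.0, 5.0]

    def test_missing_cohort_mean_rejected(self):
        import datetime as dt

        df = pd.DataFrame(
            {
                "population": ["barents"],
                "cohort": [2003],
                "hatch_date": [dt.date(2003, 7, 10)],
            }
        )
        with pytest.raises(ValueError):
            relative_hatch_date(df, {("barents", 1999): 100.0})

    def test_generator_round_trip_mean(self, presets):
        cfg = presets["baltic"]
        df = generate_scenario(cfg, seed=44)
        out = relative_hatch_date(df)
        overall = out.groupby(["population", "cohort"])["hatch_doy"].mean().mean()
        # grand-mean SD ~ cohort_mean_sd/sqrt(n_cohorts) ~ 0.8 days
        assert overall == pytest.approx(cfg.mean_hatch_doy, abs=2.5)
        percohort = out.groupby("cohort")["rel_hatch_date"].mean()
        np.testing.assert_allclose(percohort, 0.0, atol=1e-9)


@pytest.fixture(scope="module")
def pooled_resid(presets):
    frames = [
        generate_scenario(presets[n], seed=45, scale=0.5)
        for n in ("barents", "baltic", "northsea")
    ]
    pooled = pd.concat(frames, ignore_index=True)
    resid = compute_residuals(pooled, _mass_fits(pooled, presets["barents"]), "mass_g")
    return relative_hatch_date(resid)


class TestResidualLmm:
    def test_full_model_fits_and_tests(self, pooled_resid):
        summ = fit_residual_lmm(pooled_resid)
        assert summ.converged
        assert set(summ.f_tests["term"]) == {
            "C(population)",
            "C(sex)",
            "rel_hatch_date",
            "C(population):rel_hatch_date",
        }
        assert ((summ.f_tests["p"] >= 0) & (summ.f_tests["p"] <= 1)).all()

    def test_slope_invariant_to_hatch_date_shift(self, pooled_resid):
        shifted = pooled_resid.copy()
        shifted["rel_hatch_date"] = shifted["rel_hatch_date"]  # already centred
        base = fit_residual_lmm(pooled_resid)
        # add a constant to every hatch date: re-centering must absorb it
        import datetime as dt

        moved = pooled_resid.copy()
        moved["hatch_date"] = [
            d + dt.timedelta(days=7) for d in moved["hatch_date"]
        ]
        moved = relative_hatch_date(moved.drop(columns=["rel_hatch_date", "hatch_doy"]))
        again = fit_residual_lmm(moved)
        s1 = hatch_slopes(base, ["barents", "baltic", "northsea"])
        s2 = hatch_slopes(again, ["barents", "baltic", "northsea"])
        np.testing.assert_allclose(s1["slope"], s2["slope"], rtol=1e-6)

    def test_interaction_without_mains_rejected(self, pooled_resid):
        with pytest.raises(ValueError):
            fit_residual_lmm(pooled_resid, ("population", "population:rel_hatch_date"))

    def test_coefficients_match_gls_oracle(self):
        # tiny balanced design; with the fitted variance components the
        # mixed-model fixed effects must equal the direct GLS solve
        rng = np.random.default_rng(7)
        cohorts, nests_per, per_nest = 4, 3, 4
        rows = []
        for c in range(cohorts):
            bc = rng.normal(0, 5.0)
            for n_ in range(nests_per):
                bn = rng.normal(0, 8.0)
                for g in range(per_nest):
                    x = rng.normal(0, 3.0)
                    rows.append(
                        {
                            "population": "one",
                            "sex": "male",
                            "cohort": 2000 + c,
                            "nest_id": f"c{c}n{n_}",
                            "rel_hatch_date": x,
                            "residual": 2.0 - 1.5 * x + bc + bn + rng.normal(0, 6.0),
                        }
                    )
        df = pd.DataFrame(rows)
        summ = fit_residual_lmm(df, ("rel_hatch_date",))
        vc = summ.variance_components
        X = np.column_stack([np.ones(len(df)), df["rel_hatch_date"]])
        Zc = pd.get_dummies(df["cohort"]).to_numpy(float)
        Zn = pd.get_dummies(df["nest_id"]).to_numpy(float)
        beta = gls_coefficients(
            df["residual"].to_numpy(), X, Zc, Zn,
            vc["var_cohort"], vc.get("var_nest", 0.0), vc["var_residual"],
        )
        np.testing.assert_allclose(summ.params.to_numpy(), beta, rtol=1e-4)


class TestBackwardSelection:
    def test_strong_interaction_retained(self, presets):
        frames = [
            generate_scenario(presets[n], seed=46, scale=0.5)
            for n in ("barents", "baltic", "northsea")
        ]
        pooled = pd.concat(frames, ignore_index=True)
        resid = relative_hatch_date(
            compute_residuals(pooled, _mass_fits(pooled, presets["barents"]), "mass_g")
        )
        selected, trace = backward_aic_select(resid)
        assert "population:rel_hatch_date" in selected.terms
        assert {"population", "rel_hatch_date"} <= set(selected.terms)

    def test_aic_trace_arithmetic(self, presets):
        frames = [
            generate_scenario(presets[n], seed=47, scale=0.3)
            for n in ("barents", "northsea")
        ]
        pooled = pd.concat(frames, ignore_index=True)
        resid = relative_hatch_date(
            compute_residuals(pooled, _mass_fits(pooled, presets["barents"]), "mass_g")
        )
        _, trace = backward_aic_select(resid)
        for row in trace.itertuples(index=False):
            assert row.aic == pytest.approx(-2 * row.loglik + 2 * row.n_params)

    def test_pure_noise_selects_intercept_only(self, presets):
        # with no fixed-effect signal the majority of replicates should
        # strip every fixed term
        from dataclasses import replace

        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            frames = []
            for name in ("barents", "northsea"):
                cfg = with_trait(
                    presets[name], "mass_g", hatchdate_slope=0.0,
                    true_k={"male": 0.045, "female": 0.045},
                )
                cfg = replace(cfg, n_cohorts=4)
                frames.append(
                    generate_scenario(cfg, seed=900 + seed, scale=0.35)
                )
            pooled = pd.concat(frames, ignore_index=True)
            spec = presets["barents"].trait("mass_g")
            fits = {
                s: fit_fixed_gompertz(pooled, "mass_g", s, spec.adult_A[s], spec.hatch_I)
                for s in ("male", "female")
            }
            resid = relative_hatch_date(compute_residuals(pooled, fits, "mass_g"))
            selected, _ = backward_aic_select(resid)
            if selected.terms == ():
                wins += 1
        assert wins > n_rep / 2


class TestAnnualTrend:
    def test_injected_drift_recovered(self, presets):
        from dataclasses import replace

        covered = 0
        n_rep = 15
        for seed in range(n_rep):
            cfg = replace(presets["baltic"], annual_trend={"mass_g": -5.6})
            df = generate_scenario(cfg, seed=700 + seed, scale=0.5)
            resid = compute_residuals(df, _mass_fits(df, cfg), "mass_g")
            tr = annual_trend(resid)
            if tr["lo95"] <= -5.6 <= tr["hi95"]:
                covered += 1
        assert covered >= 12

    def test_no_drift_covers_zero(self, presets):
        df = generate_scenario(presets["baltic"], seed=48, scale=0.5)
        resid = compute_residuals(df, _mass_fits(df, presets["baltic"]), "mass_g")
        tr = annual_trend(resid)
        assert tr["lo95"] <= 0.0 <= tr["hi95"] or abs(tr["slope_per_year"]) < 3 * tr["se"]

    def test_total_change_consistency(self):
        # a -5.6 g/year drift over a 15-cohort span implies ~-84 g in total
        assert -5.6 * 15 == pytest.approx(-84.0)

    def test_too_few_cohorts_rejected(self, presets):
        from dataclasses import replace

        cfg = replace(presets["northsea"], n_cohorts=2)
        df = generate_scenario(cfg, seed=49)
        resid = compute_residuals(df, _mass_fits(df, cfg), "mass_g")
        with pytest.raises(ValueError):
            annual_trend(resid)
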
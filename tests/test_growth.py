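import numpy as np
import pandas as pd
import pytest

from goslinggrowth.growth import (
    GompertzParams,
    attach_time_axis,
    fit_fixed_gompertz,
    fit_population_contrast,
    fit_random_gompertz,
    gompertz_size,
)
from goslinggrowth.synthetic import generate_scenario

from conftest import noise_free, with_trait
from _oracles import golden_section_k, quadrature_marginal_loglik


class TestGompertzCurve:
    def test_hatch_size_at_zero(self):
        assert gompertz_size(2000.0, 65.0, 0.056, 0.0) == pytest.approx(65.0)

    def test_zero_growth_coefficient(self):
        t = np.array([0.0, 10.0, 50.0])
        np.testing.assert_allclose(gompertz_size(2000.0, 65.0, 0.0, t), 65.0)

    def test_monotone_and_bounded(self):
        t = np.linspace(0, 200, 400)
        y = gompertz_size(2000.0, 65.0, 0.056, t)
        assert np.all(np.diff(y) > 0)
        assert y[-1] < 2000.0

    def test_matches_arbitrary_precision_evaluation(self):
        import sympy

        A, I, k = 2000, 65, sympy.Rational(56, 1000)
        for t in (1, 7, 29, 63):
            exact = float(
                sympy.N(A * sympy.exp(sympy.log(sympy.Rational(I, A))
                                      * sympy.exp(-k * t)), 30)
            )
            assert gompertz_size(2000.0, 65.0, 0.056, float(t)) == pytest.approx(
                exact, rel=1e-12
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gompertz_size(100.0, 100.0, 0.05, 1.0)  # I == A
        with pytest.raises(ValueError):
            gompertz_size(100.0, 10.0, 0.05, -1.0)
        with pytest.raises(ValueError):
            GompertzParams(A=50.0, I=60.0, k=0.05)


class TestFixedFit:
    def test_noise_free_recovery_exact(self, barents_noise_free):
        df = generate_scenario(barents_noise_free, seed=2, round_measurements=False)
        spec = barents_noise_free.trait("mass_g")
        fit = fit_fixed_gompertz(df, "mass_g", "male", spec.adult_A["male"], spec.hatch_I)
        assert fit.k == pytest.approx(spec.true_k["male"], rel=1e-6)
        assert fit.converged

    def test_matches_golden_section_oracle(self, presets):
        df = generate_scenario(presets["northsea"], seed=9)
        spec = presets["northsea"].trait("head_mm")
        fit = fit_fixed_gompertz(df, "head_mm", "female", spec.adult_A["female"], spec.hatch_I)
        sub = df[(df["sex"] == "female") & (df["age_days"] > 0)]
        k_oracle = golden_section_k(
            sub["head_mm"].to_numpy(float),
            sub["age_days"].to_numpy(float),
            spec.adult_A["female"],
            spec.hatch_I,
        )
        assert fit.k == pytest.approx(k_oracle, rel=1e-5)

    def test_aic_definition(self, presets):
        df = generate_scenario(presets["barents"], seed=4)
        spec = presets["barents"].trait("mass_g")
        fit = fit_fixed_gompertz(df, "mass_g", "male", spec.adult_A["male"], spec.hatch_I)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 2)


class TestRandomFit:
    def test_degenerate_nesting_matches_fixed_fit(self, presets):
        cfg = with_trait(
            noise_free(presets["barents"]), "mass_g", sd_residual=40.0
        )
        df = generate_scenario(cfg, seed=6, round_measurements=False)
        spec = cfg.trait("mass_g")
        fixed = fit_fixed_gompertz(df, "mass_g", "male", spec.adult_A["male"], spec.hatch_I)
        random = fit_random_gompertz(
            df, "mass_g", "male", spec.adult_A["male"], spec.hatch_I, compute_se=False
        )
        assert random.k == pytest.approx(fixed.k, abs=1e-4)
        assert random.variance_components["sd_cohort"] < 1e-3
        assert random.variance_components["sd_nest"] < 1e-3

    def test_laplace_matches_quadrature_on_tiny_instance(self, tiny_config):
        df = generate_scenario(tiny_config, seed=12)
        spec = tiny_config.trait("mass_g")
        fit = fit_random_gompertz(
            df, "mass_g", "male", spec.adult_A["male"], spec.hatch_I, compute_se=False
        )
        vc = fit.variance_components
        exact = quadrature_marginal_loglik(
            df, "mass_g", "male", spec.adult_A["male"], spec.hatch_I,
            fit.k, max(vc["sd_cohort"], 1e-5), max(vc["sd_nest"], 1e-5),
            vc["sd_residual"],
        )
        assert fit.loglik == pytest.approx(exact, abs=0.1)

    def test_loglik_at_optimum_beats_generating_parameters(self, presets):
        # likelihood sanity: the fitted optimum cannot fall meaningfully
        # below the marginal likelihood at the generating parameter values
        from goslinggrowth.growth import marginal_loglik

        cfg = presets["barents"]
        spec = cfg.trait("mass_g")
        gaps = []
        for seed in (31, 32, 33, 34, 35):
            df = generate_scenario(cfg, seed=seed, scale=0.5)
            fit = fit_random_gompertz(
                df, "mass_g", "male", spec.adult_A["male"], spec.hatch_I,
                compute_se=False,
            )
            at_truth = marginal_loglik(
                df, "mass_g", "male", spec.adult_A["male"], spec.hatch_I,
                spec.true_k["male"], spec.sd_cohort, spec.sd_nest,
                spec.sd_residual,
            )
            gaps.append(fit.loglik - at_truth)
        assert np.mean(gaps) >= -0.5

    def test_aic_matches_hand_computation(self, tiny_config):
        df = generate_scenario(tiny_config, seed=12)
        spec = tiny_config.trait("mass_g")
        fit = fit_random_gompertz(
            df, "mass_g", "male", spec.adult_A["male"], spec.hatch_I, compute_se=False
        )
        # 1 fixed effect + 3 variance parameters
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 4)


class TestContrast:
    def test_dummy_coding_matches_separate_fits(self, presets):
        frames = []
        for name in ("barents", "baltic"):
            cfg = noise_free(presets[name])
            frames.append(
                generate_scenario(cfg, seed=13, scale=0.3, round_measurements=False)
            )
        pooled = pd.concat(frames, ignore_index=True)
        spec = presets["barents"].trait("mass_g")
        A, I = spec.adult_A["male"], spec.hatch_I
        joint, _ = fit_population_contrast(
            pooled, "mass_g", "male", A, I, reference="barents", compute_se=False
        )
        separate = fit_fixed_gompertz(
            frames[1], "mass_g", "male", A, I
        )
        assert joint.fixed_effects["k"] + joint.fixed_effects["k_baltic"] == pytest.approx(
            separate.k, rel=1e-6
        )

    def test_contrast_table_antisymmetry_and_bounds(self, presets):
        frames = [
            generate_scenario(presets[n], seed=14, scale=0.3)
            for n in ("barents", "baltic", "northsea")
        ]
        pooled = pd.concat(frames, ignore_index=True)
        spec = presets["barents"].trait("mass_g")
        _, con = fit_population_contrast(
            pooled, "mass_g", "male", spec.adult_A["male"], spec.hatch_I
        )
        assert set(con.rows["pop_a"]) <= {"baltic", "northsea"}
        assert ((con.rows["p"] >= 0) & (con.rows["p"] <= 1)).all()

    def test_missing_reference_rejected(self, presets):
        df = generate_scenario(presets["baltic"], seed=15, scale=0.2)
        spec = presets["baltic"].trait("mass_g")
        with pytest.raises(ValueError):
            fit_population_contrast(
                df, "mass_g", "male", spec.adult_A["male"], spec.hatch_I,
                reference="barents",
            )


class TestTimeAxis:
    def test_age_axis_is_identity(self, presets):
        df = generate_scenario(presets["northsea"], seed=16, scale=0.3)
        out = attach_time_axis(df, "age_days")
        np.testing.assert_allclose(out["t"], df["age_days"].astype(float))

    def test_polar_day_hours_are_24_per_day(self, presets):
        import datetime as dt

        cfg = presets["barents"]
        df = pd.DataFrame(
            {
                "population": ["barents"],
                "hatch_date": [dt.date(2010, 6, 25)],
                "capture_date": [dt.date(2010, 7, 15)],
                "age_days": [20],
            }
        )
        out = attach_time_axis(
            df, "daylight_hours", (cfg.latitude_deg, cfg.longitude_deg)
        )
        assert out["t"].iloc[0] == pytest.approx(480.0)

    def test_missing_coordinates_rejected(self, presets):
        df = generate_scenario(presets["northsea"], seed=17, scale=0.2)
        with pytest.raises(ValueError):
            attach_time_axis(df, "daylight_hours")
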
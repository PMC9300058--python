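from __future__ import annotations

from dataclasses import replace

import pytest

from goslinggrowth.scenarios import ScenarioConfig, TraitSpec, load_all_presets


@pytest.fixture(scope="session")
def presets() -> dict[str, ScenarioConfig]:
    return load_all_presets()


def noise_free(config: ScenarioConfig) -> ScenarioConfig:
    """Copy of a scenario with every stochastic size component switched off."""
    traits = {
        name: replace(
            spec, sd_cohort=0.0, sd_nest=0.0, sd_residual=0.0, hatchdate_slope=0.0
        )
        for name, spec in config.traits.items()
    }
    return replace(config, traits=traits)


def with_trait(config: ScenarioConfig, trait: str, **changes) -> ScenarioConfig:
    """Copy of a scenario with one trait's spec fields overridden."""
    traits = dict(config.traits)
    traits[trait] = replace(traits[trait], **changes)
    return replace(config, traits=traits)


@pytest.fixture(scope="session")
def barents_noise_free(presets):
    return noise_free(presets["barents"])


@pytest.fixture(scope="session")
def tiny_config(presets) -> ScenarioConfig:
    """2 cohorts x 2 nests x ~3 goslings: small enough for exact quadrature."""
    cfg = presets["barents"]
    return replace(cfg, n_cohorts=2, nests_per_cohort=2, brood_size_mean=3.0)
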
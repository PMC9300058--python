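"""Colony scenario configuration for the synthetic gosling generator.

A scenario describes one breeding colony: its coordinates, the
nest-within-cohort sampling structure, the capture-age distribution, and
the per-trait growth parameters (asymptote ``A``, hatch size ``I``, growth
coefficient ``k`` per sex, random-effect SDs and measurement noise).

Three presets ship with the package (``barents``, ``baltic``,
``northsea``), emulating barnacle goose colonies at the Barents Sea,
the Baltic (Gotland) and the North Sea (Netherlands).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

SEXES = ("male", "female")
TRAITS = ("mass_g", "head_mm", "tarsus_mm")

#: grid (and the <600 g / >600 g mass split) of the field instruments
MASS_GRID_FINE_G = 5.0
MASS_GRID_COARSE_G = 10.0
MASS_SPLIT_G = 600.0
TARSUS_GRID_MM = 0.1
HEAD_GRID_MM = 1.0


class ScenarioError(ValueError):
    """Raised for an inconsistent scenario configuration."""


@dataclass(frozen=True)
class TraitSpec:
    """Growth-curve truth for one biometric trait.

    ``adult_A`` and ``true_k`` are per sex; hatchlings cannot be sexed at
    day 0, so ``hatch_I`` is shared between sexes.  ``true_k_daylight`` is
    the growth coefficient on the accumulated-daylight clock (per daylight
    hour); ``sd_cohort``/``sd_nest`` are SDs of the Gaussian random effects
    added to ``k`` (age-clock units, 1/day); ``sd_residual`` is the
    measurement-level residual SD in trait units; ``hatchdate_slope`` is
    the additive size effect per day of relative hatch date.
    """

    adult_A: dict[str, float]
    hatch_I: float
    true_k: dict[str, float]
    true_k_daylight: dict[str, float]
    sd_cohort: float
    sd_nest: float
    sd_residual: float
    hatchdate_slope: float

    def __post_init__(self) -> None:
        for sex in SEXES:
            if sex not in self.adult_A or sex not in self.true_k:
                raise ScenarioError(f"trait spec missing sex {sex!r}")
            if not 0 < self.hatch_I < self.adult_A[sex]:
                raise ScenarioError(
                    f"hatch size I={self.hatch_I} must lie in (0, A={self.adult_A[sex]})"
                )
            if self.true_k[sex] <= 0:
                raise ScenarioError("true_k must be positive")
        for name in ("sd_cohort", "sd_nest", "sd_residual"):
            if getattr(self, name) < 0:
                raise ScenarioError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    population: str
    latitude_deg: float
    longitude_deg: float
    n_cohorts: int
    nests_per_cohort: int
    brood_size_mean: float
    n_goslings_target: int
    mean_hatch_doy: int
    cohort_mean_sd_days: float
    hatch_sd_days: float
    capture_age_median: int
    capture_age_min: int
    capture_age_max: int
    first_year: int
    traits: dict[str, TraitSpec] = field(default_factory=dict)
    #: optional linear drift of trait size across cohort years (units/year),
    #: e.g. {"mass_g": -5.6}; applied to the residual part of each record
    annual_trend: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.latitude_deg) > 90:
            raise ScenarioError("latitude out of range")
        if self.n_cohorts < 1 or self.nests_per_cohort < 1:
            raise ScenarioError("need at least one cohort and one nest")
        if self.brood_size_mean < 1:
            raise ScenarioError("brood_size_mean must be >= 1")
        if not (self.capture_age_min <= self.capture_age_median <= self.capture_age_max):
            raise ScenarioError("capture ages must satisfy min <= median <= max")
        if self.capture_age_min < 0:
            raise ScenarioError("capture ages must be non-negative")
        if self.hatch_sd_days < 0 or self.cohort_mean_sd_days < 0:
            raise ScenarioError("hatch-date SDs must be >= 0")
        for trait in self.traits:
            if trait not in TRAITS:
                raise ScenarioError(f"unknown trait {trait!r}")

    def trait(self, name: str) -> TraitSpec:
        try:
            return self.traits[name]
        except KeyError:
            raise ScenarioError(f"scenario has no trait {name!r}") from None

    def to_dict(self) -> dict:
        return asdict(self)


def _build(doc: Mapping) -> ScenarioConfig:
    doc = dict(doc)
    traits = {name: TraitSpec(**spec) for name, spec in doc.pop("traits").items()}
    return ScenarioConfig(traits=traits, **doc)


def load_scenario(source: str | Path) -> ScenarioConfig:
    """Load a scenario from a YAML file path or a shipped preset name.

    ``source`` may be ``"barents"``, ``"baltic"``, ``"northsea"`` or any
    path to a YAML file with the same schema.
    """
    name = str(source)
    if name in PRESET_NAMES:
        text = (
            resources.files("goslinggrowth").joinpath(f"presets/{name}.yaml").read_text()
        )
    else:
        path = Path(source)
        if not path.exists():
            raise ScenarioError(f"no such scenario preset or file: {source}")
        text = path.read_text()
    return _build(yaml.safe_load(text))


def save_scenario(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


PRESET_NAMES = ("barents", "baltic", "northsea")


def load_all_presets() -> dict[str, ScenarioConfig]:
    return {name: load_scenario(name) for name in PRESET_NAMES}
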
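"""Synthetic school-stage survey data.

Generates per-stage tables with the statistical structure the analysis
assumes — a linear outcome model with i.i.d. Gaussian noise — calibrated
so that covariate and outcome moments match the descriptive statistics
of the surveyed primary / junior / senior cohorts. Covariates are drawn
independently; the weekly-exercise item is a discretised draw on the
0-7 days scale, questionnaire scores are truncated normals on their
positive scales.

Discretisation note: rounding a normal draw to whole days inflates its
variance by about 1/12 (the grouped-data correction), so the generator
draws with a deflated standard deviation ``sqrt(sd^2 - 1/12)`` to land
the rounded sample back on the target spread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .data import StudyTable
from .errors import ScenarioError

__all__ = [
    "CovariateSpec",
    "StageScenario",
    "generate",
    "replicate_study",
    "load_scenarios",
    "get_scenario",
    "PRESET_NAMES",
]

STAGES = ("primary", "junior", "senior")


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal target for one simulated covariate.

    ``integer=True`` with finite bounds models count items such as
    exercise days per week (0-7); continuous scores use ``lower=0`` and
    no upper bound.
    """

    name: str
    mean: float
    sd: float
    lower: float = 0.0
    upper: float | None = None
    integer: bool = False

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ScenarioError(f"covariate '{self.name}' needs sd > 0, got {self.sd}")
        hi = np.inf if self.upper is None else self.upper
        if not self.lower <= self.mean <= hi:
            raise ScenarioError(
                f"covariate '{self.name}' target mean {self.mean} lies outside "
                f"its support [{self.lower}, {hi}]"
            )


@dataclass(frozen=True)
class StageScenario:
    """Generative recipe for one school stage.

    ``true_beta`` is aligned with ``covariate_specs`` and is expressed in
    acuity units per covariate unit; ``intercept`` and ``noise_sd`` are in
    acuity units on the decimal 5-point logarithmic scale.
    """

    stage: str
    n: int
    covariate_specs: tuple[CovariateSpec, ...]
    true_beta: tuple[float, ...]
    intercept: float
    noise_sd: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ScenarioError(f"stage must be one of {STAGES}, got '{self.stage}'")
        if self.n <= 0:
            raise ScenarioError(f"sample size must be positive, got {self.n}")
        if self.noise_sd <= 0:
            raise ScenarioError(f"noise_sd must be positive, got {self.noise_sd}")
        if len(self.true_beta) != len(self.covariate_specs):
            raise ScenarioError(
                f"{len(self.true_beta)} coefficients for "
                f"{len(self.covariate_specs)} covariates"
            )
        names = [c.name for c in self.covariate_specs]
        if len(set(names)) != len(names):
            raise ScenarioError(f"duplicate covariate names in {names}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariate_specs)


def _draw_covariate(spec: CovariateSpec, n: int, rng: np.random.Generator):
    if spec.integer:
        # deflate so the rounded draw hits the target sd (Sheppard correction)
        draw_sd = float(np.sqrt(max(spec.sd**2 - 1.0 / 12.0, 1e-4)))
        x = np.rint(rng.normal(spec.mean, draw_sd, size=n))
    else:
        x = rng.normal(spec.mean, spec.sd, size=n)
    hi = np.inf if spec.upper is None else spec.upper
    return np.clip(x, spec.lower, hi)


def generate(scenario: StageScenario) -> StudyTable:
    """Draw one survey table: covariates, then the linear outcome.

    Deterministic for a fixed scenario (the seed is part of the
    scenario). The outcome is ``intercept + X @ true_beta + noise`` with
    i.i.d. N(0, noise_sd^2) errors.
    """
    rng = np.random.default_rng(scenario.seed)
    cols = [_draw_covariate(c, scenario.n, rng) for c in scenario.covariate_specs]
    x = np.column_stack(cols)
    noise = rng.normal(0.0, scenario.noise_sd, size=scenario.n)
    y = scenario.intercept + x @ np.asarray(scenario.true_beta) + noise
    return StudyTable(
        outcome=y,
        covariates=x,
        names=scenario.names,
        stage_label=scenario.stage,
    )


def replicate_study(
    scenario: StageScenario, n_reps: int, base_seed: int
) -> list[StudyTable]:
    """Independent replicate tables with seeds ``base_seed + rep``."""
    if n_reps < 1:
        raise ScenarioError(f"n_reps must be >= 1, got {n_reps}")
    return [
        generate(replace(scenario, seed=(base_seed + rep) % 2**31))
        for rep in range(n_reps)
    ]


def _scenario_from_dict(raw: dict) -> StageScenario:
    specs = tuple(CovariateSpec(**c) for c in raw["covariates"])
    beta_map = raw.get("true_beta", {})
    beta = tuple(float(beta_map.get(c.name, 0.0)) for c in specs)
    return StageScenario(
        stage=raw["stage"],
        n=int(raw["n"]),
        covariate_specs=specs,
        true_beta=beta,
        intercept=float(raw["intercept"]),
        noise_sd=float(raw["noise_sd"]),
        seed=int(raw.get("seed", 0)),
    )


def load_scenarios() -> dict[str, StageScenario]:
    """All named presets shipped with the package."""
    text = resources.files(__package__).joinpath("presets.json").read_text("utf-8")
    return {name: _scenario_from_dict(raw) for name, raw in json.loads(text).items()}


PRESET_NAMES = (
    "primary_null",
    "junior_paper",
    "senior_paper",
    "strong_single",
    "pure_null",
)


def get_scenario(
    name: str, seed: int | None = None, n: int | None = None
) -> StageScenario:
    """Fetch a preset by name, optionally overriding its seed or size."""
    scenarios = load_scenarios()
    if name not in scenarios:
        raise ScenarioError(
            f"unknown scenario '{name}'; available: {sorted(scenarios)}"
        )
    sc = scenarios[name]
    if seed is not None:
        sc = replace(sc, seed=int(seed))
    if n is not None:
        sc = replace(sc, n=int(n))
    return sc
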
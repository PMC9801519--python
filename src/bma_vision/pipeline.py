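"""End-to-end stage analysis and report rendering.

``run_stage`` takes a :class:`RunConfig` pointing at a CSV file or a
named synthetic preset, runs the exact BMA pipeline (with an optional
MC3 cross-check), and returns a :class:`StageReport` carrying the four
report surfaces:

* ``variable_table``  — one row per covariate: inclusion probability,
  model-averaged mean and SD, sign-consistency and evidence grade,
  sorted by inclusion probability;
* ``top_models_table`` — the top-m models as 0/1 inclusion indicators
  with their exact (and, when the sampler ran, MC3) posterior
  probabilities;
* ``size_distribution`` — posterior probability of each model size;
* ``inclusion_map`` — every model ordered by posterior probability,
  with signed inclusion entries (+1 positive conditional mean, -1
  negative, 0 excluded) and cumulative probability.

``render_report`` writes them as deterministic CSV files plus a JSON
run manifest; timing goes to stderr only so re-runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BMAResult,
    ENUMERATION_CAP,
    DEFAULT_THRESHOLDS,
    average,
    enumerate_models,
    fit_all_models,
    posterior_model_probs,
)
from .data import StudyTable, read_study_csv, validate_and_center
from .errors import ConfigError
from .mc3 import SamplerSettings, SamplerTrace, convergence_report, mc3_run
from .priors import PriorSettings
from .synthetic import PRESET_NAMES, generate, get_scenario, load_scenarios

__all__ = ["RunConfig", "StageReport", "run_stage", "render_report", "run_all_stages"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one stage analysis needs.

    ``input`` is either a path to a CSV or the name of a shipped
    synthetic preset. For presets the outcome/covariate columns are
    implied; ``seed`` (if given) overrides the preset's seed.
    """

    input: str
    outcome_column: str = "acuity"
    covariate_columns: tuple[str, ...] | None = None
    g_rule: str = "uip"
    g: float | None = None
    sampler: bool = False
    sampler_settings: SamplerSettings = field(default_factory=SamplerSettings)
    top_m: int = 3
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    seed: int | None = None
    stage_label: str = ""

    def __post_init__(self) -> None:
        if self.covariate_columns and self.outcome_column in self.covariate_columns:
            raise ConfigError(
                f"outcome column '{self.outcome_column}' is also listed as a covariate"
            )
        t = self.thresholds
        if not (0 < t[0] < t[1] < t[2] < 1):
            raise ConfigError(
                f"evidence thresholds must be strictly increasing in (0,1), got {t}"
            )
        if self.top_m < 1:
            raise ConfigError(f"top_m must be >= 1, got {self.top_m}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        """Load a config from a JSON file mirroring the CLI flags."""
        raw = json.loads(Path(path).read_text("utf-8"))
        if "sampler_settings" in raw:
            raw["sampler_settings"] = SamplerSettings(**raw["sampler_settings"])
        if "covariate_columns" in raw and raw["covariate_columns"] is not None:
            raw["covariate_columns"] = tuple(raw["covariate_columns"])
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(**raw)


@dataclass(frozen=True)
class StageReport:
    """All report surfaces for one stage, plus the raw result objects."""

    variable_table: pd.DataFrame
    top_models_table: pd.DataFrame
    size_distribution: pd.DataFrame
    inclusion_map: pd.DataFrame
    manifest: dict
    result: BMAResult
    trace: SamplerTrace | None = None
    diagnostics: dict | None = None


def _load_table(config: RunConfig) -> StudyTable:
    if config.input in load_scenarios():
        scenario = get_scenario(config.input, seed=config.seed)
        return generate(scenario)
    path = Path(config.input)
    if not path.exists():
        raise ConfigError(
            f"input '{config.input}' is neither a readable file nor one of the "
            f"presets {sorted(PRESET_NAMES)}"
        )
    covs = list(config.covariate_columns) if config.covariate_columns else None
    return read_study_csv(
        path, config.outcome_column, covs, stage_label=config.stage_label
    )


def run_stage(config: RunConfig) -> StageReport:
    """Run the full analysis for one school stage."""
    t0 = time.perf_counter()
    table = _load_table(config)
    prior = PriorSettings(g_rule=config.g_rule, g=config.g)
    centered, center_report = validate_and_center(table)
    g_value = prior.resolve_g(table.n, table.s)

    trace = None
    diagnostics = None
    if table.s <= ENUMERATION_CAP:
        models = enumerate_models(table.s)
        fits = fit_all_models(centered, models, prior)
        pmp = posterior_model_probs(fits, prior)
        if config.sampler:
            trace = mc3_run(centered, prior, config.sampler_settings)
            diagnostics = convergence_report(trace, models, pmp)
    else:
        if not config.sampler:
            raise ConfigError(
                f"s={table.s} exceeds the enumeration cap ({ENUMERATION_CAP}) "
                "and the sampler is disabled"
            )
        # sampler-only regime: frequencies stand in for exact weights and
        # averaging runs over the visited models
        trace = mc3_run(centered, prior, config.sampler_settings)
        models = sorted(trace.visit_counts)
        fits = fit_all_models(centered, models, prior)
        pmp = trace.pmp_vector(models)
        diagnostics = convergence_report(trace)

    result = average(fits, pmp, table.names, thresholds=config.thresholds)

    order = np.argsort(-result.pip, kind="stable")
    variable_table = pd.DataFrame(
        {
            "variable": [table.names[j] for j in order],
            "pip": result.pip[order],
            "post_mean": result.post_mean[order],
            "post_sd": result.post_sd[order],
            "sign_consistency": result.sign_consistency[order],
            "evidence": [result.evidence_grade[j] for j in order],
        }
    )

    rank = np.argsort(-pmp, kind="stable")
    m = min(config.top_m, len(models))
    top = rank[:m]
    top_cols = {f"model_{i + 1}": None for i in range(m)}
    rows = {name: [] for name in table.names}
    for i, idx in enumerate(top):
        for j, name in enumerate(table.names):
            rows[name].append(1.0 if j in models[idx] else 0.0)
    top_data = {"variable": list(table.names) + ["PMP (exact)"]}
    exact_row = [float(pmp[idx]) for idx in top]
    for i in range(m):
        top_cols[f"model_{i + 1}"] = [rows[name][i] for name in table.names] + [
            exact_row[i]
        ]
    if trace is not None and table.s <= ENUMERATION_CAP:
        top_data["variable"].append("PMP (MCMC)")
        mcmc = trace.pmp_vector(models)
        for i, idx in enumerate(top):
            top_cols[f"model_{i + 1}"].append(float(mcmc[idx]))
    top_models_table = pd.DataFrame({"variable": top_data["variable"], **top_cols})

    size_distribution = pd.DataFrame(
        {
            "model_size": np.arange(len(result.size_distribution)),
            "posterior_probability": result.size_distribution,
        }
    )

    incl_rows = []
    cum = 0.0
    for r, idx in enumerate(rank, start=1):
        fit = fits[idx]
        cum += float(pmp[idx])
        row = {"rank": r, "pmp": float(pmp[idx]), "cumulative_pmp": cum}
        signs = {name: 0 for name in table.names}
        for pos, j in enumerate(fit.model.included):
            signs[table.names[j]] = 1 if fit.coef_mean[pos] >= 0 else -1
        row.update(signs)
        incl_rows.append(row)
    inclusion_map = pd.DataFrame(incl_rows)

    wall = time.perf_counter() - t0
    manifest = {
        "input": config.input,
        "stage": table.stage_label or config.stage_label,
        "n": table.n,
        "s": table.s,
        "n_dropped": table.n_dropped,
        "covariates": list(table.names),
        "g_rule": config.g_rule,
        "g": g_value,
        "seed": config.seed,
        "thresholds": list(config.thresholds),
        "sampler": dataclasses.asdict(config.sampler_settings)
        if config.sampler
        else None,
        "diagnostics": diagnostics,
        "outcome_mean": center_report.outcome_mean,
        "covariate_means": center_report.covariate_means,
    }
    print(
        f"[bma-vision] stage={manifest['stage'] or '?'} n={table.n} s={table.s} "
        f"dropped={table.n_dropped} g={g_value:.6g} seed={config.seed} "
        f"wall={wall:.2f}s",
        file=sys.stderr,
    )
    return StageReport(
        variable_table=variable_table,
        top_models_table=top_models_table,
        size_distribution=size_distribution,
        inclusion_map=inclusion_map,
        manifest=manifest,
        result=result,
        trace=trace,
        diagnostics=diagnostics,
    )


def render_report(report: StageReport, out_dir, fmt: str = "csv") -> list[Path]:
    """Write the report surfaces as CSV plus a JSON manifest.

    Output is deterministic: identical inputs reproduce byte-identical
    files. Returns the written paths.
    """
    if fmt != "csv":
        raise ConfigError(f"unsupported output format '{fmt}'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (
        ("variable_table", report.variable_table),
        ("top_models", report.top_models_table),
        ("size_distribution", report.size_distribution),
        ("inclusion_map", report.inclusion_map),
    ):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.17g")
        written.append(path)
    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(
        json.dumps(report.manifest, indent=2, sort_keys=True) + "\n", "utf-8"
    )
    written.append(manifest_path)
    return written


def run_all_stages(
    seed: int,
    out_dir=None,
    sampler: bool = False,
    presets: tuple[str, ...] = ("primary_null", "junior_paper", "senior_paper"),
) -> dict[str, StageReport]:
    """Run the three stage presets in one invocation.

    Each stage gets an independent seed derived from ``seed`` so no RNG
    state is shared across stages.
    """
    reports = {}
    for i, preset in enumerate(presets):
        stage_seed = int(
            np.random.SeedSequence([seed, i]).generate_state(1)[0] & 0x7FFFFFFF
        )
        config = RunConfig(
            input=preset,
            sampler=sampler,
            sampler_settings=SamplerSettings(seed=stage_seed),
            seed=stage_seed,
            stage_label=preset,
        )
        report = run_stage(config)
        if out_dir is not None:
            render_report(report, Path(out_dir) / preset)
        reports[preset] = report
    return reports
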
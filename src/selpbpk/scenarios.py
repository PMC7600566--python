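"""Scenario configuration, validation and end-to-end runs.

A scenario is a YAML (or JSON) document naming a population, a dose regimen
and a trial design.  ``run_scenario`` executes it and writes a result bundle:
mean-subject profiles, the per-subject trial summary table, an optional
special-vs-reference comparison table, and a run manifest (package version,
seed, config hash) that makes re-runs bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .compounds import builtin_compounds, builtin_schemes
from .dermal import PatchProduct
from .engine import (CompoundModelSet, DoseRegimen, SolverSettings,
                     assemble_system, simulate)
from .errors import ConfigurationError
from .populations import mean_individual, population_presets
from .trials import population_comparison, run_virtual_trials


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    population: str
    regimen: DoseRegimen
    n_per_trial: int
    n_trials: int
    seed: int
    duration: float | None = None
    compare_to: str | None = None
    metabolite_albumin_binding: bool = False
    solver: SolverSettings = field(default_factory=SolverSettings)
    output_dir: str = "results"


def _regimen_from_mapping(entry: dict) -> DoseRegimen:
    patch = None
    if "patch" in entry and entry["patch"] is not None:
        patch = PatchProduct(**{k: v for k, v in entry["patch"].items()})
    return DoseRegimen(route=entry["route"], dose=float(entry["dose"]),
                       duration=float(entry["duration"]),
                       interval=float(entry.get("interval", 24.0)),
                       n_doses=int(entry.get("n_doses", 1)), patch=patch)


def load_scenario(path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return scenario_from_mapping(raw)


def scenario_from_mapping(raw: dict) -> ScenarioConfig:
    try:
        design = raw["trial_design"]
        if "seed" not in design:
            raise ConfigurationError("trial_design.seed is mandatory")
        solver = SolverSettings(**raw.get("solver", {}))
        return ScenarioConfig(
            name=raw["name"], population=raw["population"],
            regimen=_regimen_from_mapping(raw["regimen"]),
            n_per_trial=int(design["n_per_trial"]),
            n_trials=int(design.get("n_trials", 10)), seed=int(design["seed"]),
            duration=raw.get("duration"), compare_to=raw.get("compare_to"),
            metabolite_albumin_binding=bool(
                raw.get("metabolite_albumin_binding", False)),
            solver=solver, output_dir=raw.get("output_dir", "results"))
    except KeyError as exc:
        raise ConfigurationError(f"scenario is missing required key {exc}") from exc


def bundled_scenarios() -> dict[str, ScenarioConfig]:
    """Scenario configs shipped with the package."""
    out = {}
    base = resources.files("selpbpk.data").joinpath("scenarios")
    for entry in base.iterdir():
        if entry.name.endswith(".yaml"):
            raw = yaml.safe_load(entry.read_text())
            cfg = scenario_from_mapping(raw)
            out[cfg.name] = cfg
    return out


def validate_inputs(config: ScenarioConfig) -> dict:
    """Validation report {errors: [...], warnings: [...]} (does not raise)."""
    errors, warnings = [], []
    presets = population_presets()
    if config.population not in presets:
        errors.append(f"unknown population {config.population!r}")
    if config.compare_to is not None and config.compare_to not in presets:
        errors.append(f"unknown comparison population {config.compare_to!r}")
    if config.n_per_trial < 1 or config.n_trials < 1:
        errors.append("trial design requires n_per_trial >= 1 and n_trials >= 1")
    if config.duration is not None and config.duration < config.regimen.duration:
        errors.append("simulation duration does not cover the first administration")

    compounds = builtin_compounds()
    schemes = builtin_schemes()
    for name, scheme in schemes.items():
        total = scheme.total_percent
        if total > 100.5:
            errors.append(f"metabolism of {name} sums to {total:.2f}% > 100%")
        for p in scheme.pathways:
            if p.product not in compounds and not p.product.isupper():
                warnings.append(f"{name} pathway product {p.product} treated as sink")
    sel = compounds.get("SEL")
    if sel is not None and sel.binding is None:
        errors.append("SEL requires a plasma binding model for fu computation")
    if config.regimen.route == "transdermal" and config.regimen.patch is None:
        errors.append("transdermal regimen without patch definition")
    return {"errors": errors, "warnings": warnings}


def _config_hash(config: ScenarioConfig) -> str:
    blob = json.dumps(repr(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_scenario(config: ScenarioConfig | str | Path,
                 output_dir: str | Path | None = None) -> dict:
    """Execute a scenario and write the result bundle; returns artifact paths."""
    if not isinstance(config, ScenarioConfig):
        config = load_scenario(config)
    report = validate_inputs(config)
    if report["errors"]:
        raise ConfigurationError("; ".join(report["errors"]))

    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    presets = population_presets()
    model = CompoundModelSet()

    # mean-subject reference profile
    ind = mean_individual(presets[config.population])
    system = assemble_system(
        ind, model, config.regimen,
        metabolite_albumin_binding=config.metabolite_albumin_binding)
    result = simulate(system, duration=config.duration, settings=config.solver)
    import pandas as pd
    profile_rows = {"time_h": result.times}
    for name, profile in result.profiles.items():
        profile_rows[f"{name}_pg_ml"] = profile.conc_pg_ml
        profile_rows[f"{name}_unbound_pg_ml"] = profile.conc_unbound_pg_ml
        profile_rows[f"{name}_urine_nmol"] = profile.urine_nmol
    profiles_path = out / "profiles.csv"
    pd.DataFrame(profile_rows).to_csv(profiles_path, index=False)

    trials = run_virtual_trials(
        presets[config.population], config.regimen, config.n_per_trial,
        n_trials=config.n_trials, seed=config.seed, model=model,
        duration=config.duration,
        metabolite_albumin_binding=config.metabolite_albumin_binding,
        settings=config.solver)
    summaries_path = out / "summaries.csv"
    trials.table.to_csv(summaries_path, index=False)

    artifacts = {"profiles": str(profiles_path), "summaries": str(summaries_path)}
    if config.compare_to:
        reference = run_virtual_trials(
            presets[config.compare_to], config.regimen, config.n_per_trial,
            n_trials=config.n_trials, seed=config.seed, model=model,
            duration=config.duration,
            metabolite_albumin_binding=config.metabolite_albumin_binding,
            settings=config.solver)
        comparison = population_comparison(trials, reference)
        comparison_path = out / "comparison.csv"
        comparison.to_csv(comparison_path, index=False)
        artifacts["comparison"] = str(comparison_path)

    from . import __version__
    manifest = {
        "scenario": config.name, "package_version": __version__,
        "seed": config.seed, "config_hash": _config_hash(config),
        "population": config.population, "compare_to": config.compare_to,
        "warnings": report["warnings"],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = str(manifest_path)
    return artifacts
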
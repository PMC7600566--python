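"""Virtual population sampling: the package's synthetic-data generator.

Samples virtual individuals (demographics, CYP abundances with genotype
phenotypes, cardiac output and hepatic blood flow, GFR ratio, liver weight,
microsomal protein yield, plasma protein concentrations) for the built-in
populations: healthy adults, geriatric, adolescent (12-20 y), moderate and
severe renal impairment, and Child-Pugh B/C hepatic cirrhosis.

All continuous quantities are sampled log-normally around the preset mean
with the preset CV (mean-parameterised, so the arithmetic sample mean
converges to the preset mean); CYP2D6 individuals are assigned a metabolizer
phenotype by frequency, with poor metabolizers expressing no enzyme at all.
Cardiac output and liver weight scale allometrically with body weight
(exponent 0.75) around the sex-specific reference.  Sampling is fully
deterministic under a fixed (population, n, seed) triple.

Also provides the noisy-profile synthesiser used by the parameter-recovery
tests (multiplicative log-normal measurement error with an additive floor).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .errors import ConfigurationError

_ALLOMETRIC_EXPONENT = 0.75


@dataclass(frozen=True)
class PhenotypeClass:
    name: str
    frequency: float
    multiplier: float


@dataclass(frozen=True)
class PopulationSpec:
    """Distributional description of one virtual population."""

    name: str
    age_range: tuple[float, float]
    proportion_female: float
    body_weight: dict                  # sex -> {mean, cv}
    cardiac_output: dict               # {mean, cv}, L/h
    hepatic_flow_fraction: float       # Q_H as a fraction of cardiac output
    liver_weight: dict                 # {mean, cv}, g
    mppgl: dict                        # {mean, cv}, mg/g
    gfr_ratio: dict                    # {mean, cv}
    hematocrit: float
    macroglobulin: dict                # sex -> {mean, cv}, uM
    albumin: dict                      # {mean, cv, age_slope_per_year, age_ref}, uM
    cyp_abundance: dict                # enzyme -> {mean, cv}, pmol/mg
    phenotypes: dict = field(default_factory=dict)   # enzyme -> [PhenotypeClass]

    def __post_init__(self):
        for enzyme, classes in self.phenotypes.items():
            total = sum(c.frequency for c in classes)
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"phenotype frequencies for {enzyme} sum to {total}, expected 1")
        for entry in self._cv_entries():
            if entry["cv"] < 0:
                raise ConfigurationError("CV must be >= 0")

    def _cv_entries(self):
        yield self.cardiac_output
        yield self.liver_weight
        yield self.mppgl
        yield self.gfr_ratio
        yield self.albumin
        yield from self.body_weight.values()
        yield from self.macroglobulin.values()
        yield from self.cyp_abundance.values()

    @property
    def mean_hepatic_blood_flow(self) -> float:
        return self.cardiac_output["mean"] * self.hepatic_flow_fraction


@dataclass(frozen=True)
class Individual:
    """One realised virtual subject."""

    population: str
    index: int
    sex: str
    age: float
    body_weight: float                 # kg
    cardiac_output: float              # L/h
    hepatic_blood_flow: float          # L/h
    liver_weight: float                # g
    mppgl: float                       # mg/g
    gfr_ratio: float
    hematocrit: float
    macroglobulin: float               # uM
    albumin: float                     # uM
    cyp_abundance: dict                # enzyme -> pmol/mg (0 for PM)
    phenotype: dict = field(default_factory=dict)    # enzyme -> class name

    @property
    def protein_concentrations(self) -> dict:
        return {"macroglobulin": self.macroglobulin, "albumin": self.albumin}


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Mean-parameterised log-normal draw; degenerate at the mean for CV 0."""
    if cv == 0 or mean == 0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(np.exp(rng.normal(mu, np.sqrt(sigma2))))


def sample_individual(spec: PopulationSpec, rng: np.random.Generator,
                      index: int = 0) -> Individual:
    sex = "female" if rng.random() < spec.proportion_female else "male"
    age = float(rng.uniform(*spec.age_range))
    bw_spec = spec.body_weight[sex]
    bw = _lognormal(rng, bw_spec["mean"], bw_spec["cv"])
    size = (bw / bw_spec["mean"]) ** _ALLOMETRIC_EXPONENT

    co = size * _lognormal(rng, spec.cardiac_output["mean"], spec.cardiac_output["cv"])
    lw = size * _lognormal(rng, spec.liver_weight["mean"], spec.liver_weight["cv"])
    mppgl = _lognormal(rng, spec.mppgl["mean"], spec.mppgl["cv"])
    gfr = _lognormal(rng, spec.gfr_ratio["mean"], spec.gfr_ratio["cv"])

    mg_spec = spec.macroglobulin[sex]
    macroglobulin = _lognormal(rng, mg_spec["mean"], mg_spec["cv"])
    alb = spec.albumin
    alb_mean = alb["mean"] + alb.get("age_slope_per_year", 0.0) * (
        age - alb.get("age_ref", 35.0))
    albumin = _lognormal(rng, max(alb_mean, 1.0), alb["cv"])

    phenotype = {}
    abundance = {}
    for enzyme, dist in spec.cyp_abundance.items():
        multiplier = 1.0
        if enzyme in spec.phenotypes:
            classes = spec.phenotypes[enzyme]
            u = rng.random()
            cum = 0.0
            chosen = classes[-1]
            for cls in classes:
                cum += cls.frequency
                if u < cum:
                    chosen = cls
                    break
            phenotype[enzyme] = chosen.name
            multiplier = chosen.multiplier
        abundance[enzyme] = multiplier * _lognormal(rng, dist["mean"], dist["cv"])

    return Individual(
        population=spec.name, index=index, sex=sex, age=age, body_weight=bw,
        cardiac_output=co, hepatic_blood_flow=co * spec.hepatic_flow_fraction,
        liver_weight=lw, mppgl=mppgl, gfr_ratio=gfr, hematocrit=spec.hematocrit,
        macroglobulin=macroglobulin, albumin=albumin,
        cyp_abundance=abundance, phenotype=phenotype,
    )


def sample_population(spec: PopulationSpec, n: int, seed: int) -> list[Individual]:
    """Sample n reproducible virtual individuals from a population."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [sample_individual(spec, rng, index=i) for i in range(n)]


def mean_individual(spec: PopulationSpec, sex: str = "male") -> Individual:
    """The deterministic mean subject of a population (all CVs collapsed)."""
    co = spec.cardiac_output["mean"]
    alb = spec.albumin
    age = sum(spec.age_range) / 2.0
    return Individual(
        population=spec.name, index=-1, sex=sex, age=age,
        body_weight=spec.body_weight[sex]["mean"], cardiac_output=co,
        hepatic_blood_flow=co * spec.hepatic_flow_fraction,
        liver_weight=spec.liver_weight["mean"], mppgl=spec.mppgl["mean"],
        gfr_ratio=spec.gfr_ratio["mean"], hematocrit=spec.hematocrit,
        macroglobulin=spec.macroglobulin[sex]["mean"],
        albumin=alb["mean"] + alb.get("age_slope_per_year", 0.0) * (
            age - alb.get("age_ref", 35.0)),
        cyp_abundance={e: d["mean"] for e, d in spec.cyp_abundance.items()},
        phenotype={e: "EM" for e in spec.phenotypes},
    )


# ---------------------------------------------------------------------------
# Preset registry
# ---------------------------------------------------------------------------

def _resolve_entry(name: str, raw: dict) -> dict:
    entry = raw[name]
    if "base" in entry:
        base = copy.deepcopy(_resolve_entry(entry["base"], raw))
        merged = {**base, **{k: v for k, v in entry.items() if k != "base"}}
    else:
        merged = copy.deepcopy(entry)
    return merged


def _spec_from_entry(name: str, entry: dict) -> PopulationSpec:
    abundance = copy.deepcopy(entry["cyp_abundance"])
    for enzyme, mult in entry.get("abundance_multipliers", {}).items():
        if enzyme not in abundance:
            raise ConfigurationError(f"multiplier for unknown enzyme {enzyme}")
        abundance[enzyme] = dict(abundance[enzyme])
        abundance[enzyme]["mean"] *= mult
    phenotypes = {
        enzyme: tuple(PhenotypeClass(c["name"], c["frequency"], c["multiplier"])
                      for c in classes)
        for enzyme, classes in entry.get("phenotypes", {}).items()
    }
    return PopulationSpec(
        name=name,
        age_range=tuple(entry["age_range"]),
        proportion_female=float(entry.get("proportion_female", 0.0)),
        body_weight=entry["body_weight"],
        cardiac_output=entry["cardiac_output"],
        hepatic_flow_fraction=float(entry["hepatic_flow_fraction"]),
        liver_weight=entry["liver_weight"],
        mppgl=entry["mppgl"],
        gfr_ratio=entry["gfr_ratio"],
        hematocrit=float(entry.get("hematocrit", 0.45)),
        macroglobulin=entry["macroglobulin"],
        albumin=entry["albumin"],
        cyp_abundance=abundance,
        phenotypes=phenotypes,
    )


_PRESET_CACHE: dict[str, PopulationSpec] | None = None


def population_presets(path=None) -> dict[str, PopulationSpec]:
    """Registry of built-in population presets (loaded from the YAML file)."""
    global _PRESET_CACHE
    if path is None and _PRESET_CACHE is not None:
        return dict(_PRESET_CACHE)
    if path is None:
        text = resources.files("selpbpk.data").joinpath("populations.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    presets = {name: _spec_from_entry(name, _resolve_entry(name, raw))
               for name in raw}
    if path is None:
        _PRESET_CACHE = presets
    return dict(presets)


def individuals_frame(individuals: list[Individual]):
    """Audit dump of sampled individuals as a DataFrame (CSV-ready)."""
    import pandas as pd

    rows = []
    for ind in individuals:
        row = {
            "population": ind.population, "index": ind.index, "sex": ind.sex,
            "age": ind.age, "body_weight": ind.body_weight,
            "cardiac_output": ind.cardiac_output,
            "hepatic_blood_flow": ind.hepatic_blood_flow,
            "liver_weight": ind.liver_weight, "mppgl": ind.mppgl,
            "gfr_ratio": ind.gfr_ratio, "macroglobulin": ind.macroglobulin,
            "albumin": ind.albumin,
        }
        row.update({f"abundance_{e}": v for e, v in ind.cyp_abundance.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic noisy profiles (for parameter-recovery tests)
# ---------------------------------------------------------------------------

def synthesize_noisy_profile(true_profile, cv: float, seed: int,
                             additive_floor: float = 0.0):
    """Observed-like profile: multiplicative log-normal noise + additive floor.

    The multiplicative term has arithmetic mean 1 and coefficient of variation
    ``cv``; ``additive_floor`` adds zero-mean Gaussian noise of that SD,
    emulating assay noise near the quantification limit.  Negative results are
    clipped at zero.
    """
    if cv < 0:
        raise ConfigurationError("cv must be >= 0")
    values = np.asarray(true_profile, dtype=float)
    rng = np.random.default_rng(seed)
    if cv > 0:
        sigma2 = np.log1p(cv * cv)
        factor = np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=values.shape))
    else:
        factor = np.ones_like(values)
    noisy = values * factor
    if additive_floor > 0:
        noisy = noisy + rng.normal(0.0, additive_floor, size=values.shape)
    return np.clip(noisy, 0.0, None)
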
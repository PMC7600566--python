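"""Compound definitions, plasma protein binding, ionization and metabolism maps.

The model input set covers selegiline (SEL) and its three metabolites:
methamphetamine (MAP) and desmethylselegiline (DMS) as primary metabolites
and amphetamine (AMP) as the secondary metabolite formed from both.  All four
are monoprotic bases.  SEL binds to two plasma proteins (alpha-2-macroglobulin
preferentially, albumin weakly); the metabolites bind principally to albumin.

Internal unit conventions used throughout the package: amounts in nmol,
volumes in L, time in h.  Conversion to pg/mL happens only at the reporting
boundary (`nmol_per_l_to_pg_per_ml`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

from .errors import ConfigurationError, InputError, ValidationError

# Default healthy plasma protein concentrations (uM).  Macroglobulin means are
# literature values for healthy males/females; albumin 624 uM corresponds to
# ~41.5 g/L at MW 66.5 kDa (adult reference range 35-50 g/L).
HEALTHY_MACROGLOBULIN_UM = 3.95
HEALTHY_ALBUMIN_UM = 624.0

#: tolerance on the sum of % metabolized entries of one parent
FM_SUM_TOLERANCE = 0.5


@dataclass(frozen=True)
class PlasmaBindingModel:
    """Two-protein linear binding model.

    fu = 1 / (1 + sum_i [P_i]/K_D,i), one site per protein, non-saturable
    regime (therapeutic selegiline concentrations are pg/mL, far below K_D).
    Dissociation constants in uM.
    """

    kd_macroglobulin: float | None = None
    kd_albumin: float | None = None

    def __post_init__(self):
        for name, kd in (("kd_macroglobulin", self.kd_macroglobulin),
                         ("kd_albumin", self.kd_albumin)):
            if kd is not None and kd <= 0:
                raise ValidationError(f"{name} must be > 0, got {kd}")

    def kd_for(self, protein: str) -> float | None:
        return {"macroglobulin": self.kd_macroglobulin,
                "albumin": self.kd_albumin}.get(protein)


@dataclass(frozen=True)
class MetabolicPathway:
    """One enzyme-specific branch of a parent's hepatic metabolic clearance."""

    enzyme: str
    product: str            # compound identifier or a sink identifier (e.g. OHAMP)
    percent_contribution: float  # % of parent hepatic metabolic clearance

    def __post_init__(self):
        if self.percent_contribution < 0:
            raise ValidationError(
                f"percent_contribution must be >= 0, got {self.percent_contribution}")


@dataclass(frozen=True)
class MetabolismScheme:
    parent: str
    pathways: tuple[MetabolicPathway, ...] = ()

    def __post_init__(self):
        total = sum(p.percent_contribution for p in self.pathways)
        if total > 100.0 + FM_SUM_TOLERANCE:
            raise ValidationError(
                f"metabolism scheme of {self.parent} sums to {total:.2f}% > 100%")

    @property
    def total_percent(self) -> float:
        return sum(p.percent_contribution for p in self.pathways)


@dataclass(frozen=True)
class CompoundSpec:
    """Physicochemical, binding, clearance and distribution inputs for one molecule."""

    name: str
    molecular_weight: float          # g/mol
    log_p: float
    pka: float
    ionization_class: str = "monoprotic_base"
    fu_plasma: float = 1.0           # fraction unbound in plasma
    blood_plasma_ratio: float = 1.0
    cl_iv: float = 0.0               # systemic (plasma) clearance, L/h
    cl_renal: float = 0.0            # renal clearance, L/h
    vss: float | None = None         # L/kg (minimal-PBPK input)
    distribution_mode: str = "minimal"   # {"full", "minimal"}
    binding: PlasmaBindingModel | None = None

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise ValidationError(f"molecular_weight must be > 0 for {self.name}")
        if not 0 < self.fu_plasma <= 1:
            raise ValidationError(f"fu_plasma must be in (0,1] for {self.name}")
        if self.blood_plasma_ratio <= 0:
            raise ValidationError(f"blood_plasma_ratio must be > 0 for {self.name}")
        if self.cl_renal > self.cl_iv:
            raise ValidationError(
                f"cl_renal ({self.cl_renal}) exceeds cl_iv ({self.cl_iv}) for {self.name}")
        if self.vss is not None and self.vss <= 0:
            raise ValidationError(f"vss must be > 0 for {self.name}")
        if self.distribution_mode not in ("full", "minimal"):
            raise ValidationError(
                f"distribution_mode must be 'full' or 'minimal' for {self.name}")

    @property
    def cl_hepatic(self) -> float:
        """Systemic clearance net of the renal route (L/h, plasma basis)."""
        return self.cl_iv - self.cl_renal


# ---------------------------------------------------------------------------
# Binding / ionization operations
# ---------------------------------------------------------------------------

def fraction_unbound(binding: PlasmaBindingModel,
                     protein_concentrations: Mapping[str, float]) -> float:
    """Fraction unbound in plasma from the linear multi-protein binding model.

    fu = 1 / (1 + sum_i [P_i] / K_D,i) with concentrations and K_D in uM.
    An empty mapping returns 1.0 (fully unbound by definition).
    """
    total = 0.0
    for protein, conc in protein_concentrations.items():
        if conc < 0:
            raise InputError(f"negative concentration for {protein}: {conc}")
        kd = binding.kd_for(protein)
        if kd is None:
            raise ConfigurationError(
                f"protein '{protein}' supplied but no dissociation constant defined")
        total += conc / kd
    return 1.0 / (1.0 + total)


def fraction_unionized(pka: float, ph: float,
                       ionization_class: str = "monoprotic_base") -> float:
    """Henderson-Hasselbalch unionized fraction for a monoprotic base."""
    if ionization_class != "monoprotic_base":
        raise ConfigurationError(
            f"unsupported ionization class: {ionization_class!r}")
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def log_d(log_p: float, pka: float, ph: float,
          ionization_class: str = "monoprotic_base") -> float:
    """Distribution coefficient logD = logP + log10(fraction unionized)."""
    return log_p + math.log10(fraction_unionized(pka, ph, ionization_class))


# ---------------------------------------------------------------------------
# Metabolism scheme normalisation
# ---------------------------------------------------------------------------

def normalized_fm(scheme: MetabolismScheme) -> dict[tuple[str, str], float]:
    """Per-(enzyme, product) fraction of the parent's hepatic metabolic clearance.

    Returns percent/100 per pathway.  Any residual (100 - sum%) remains
    unassigned hepatic clearance; callers can query it via
    ``1 - sum(normalized_fm(s).values())``.
    """
    return {(p.enzyme, p.product): p.percent_contribution / 100.0
            for p in scheme.pathways}


def fm_by_product(scheme: MetabolismScheme) -> dict[str, float]:
    """Total fraction of hepatic metabolic clearance routed to each product."""
    totals: dict[str, float] = {}
    for p in scheme.pathways:
        totals[p.product] = totals.get(p.product, 0.0) + p.percent_contribution / 100.0
    return totals


# ---------------------------------------------------------------------------
# Unit conversions (reporting boundary)
# ---------------------------------------------------------------------------

def mg_to_nmol(mg: float, molecular_weight: float) -> float:
    return mg * 1.0e6 / molecular_weight


def nmol_to_mg(nmol: float, molecular_weight: float) -> float:
    return nmol * molecular_weight * 1.0e-6


def nmol_per_l_to_pg_per_ml(conc_nmol_per_l, molecular_weight: float):
    """nmol/L x g/mol = ng/L = pg/mL (numerically identical scale factor MW)."""
    return conc_nmol_per_l * molecular_weight


# ---------------------------------------------------------------------------
# Built-in registry
# ---------------------------------------------------------------------------

def _spec_from_mapping(name: str, entry: Mapping) -> tuple[CompoundSpec, MetabolismScheme]:
    binding = None
    if "binding" in entry:
        binding = PlasmaBindingModel(
            kd_macroglobulin=entry["binding"].get("kd_macroglobulin"),
            kd_albumin=entry["binding"].get("kd_albumin"),
        )
    spec = CompoundSpec(
        name=name,
        molecular_weight=float(entry["molecular_weight"]),
        log_p=float(entry["log_p"]),
        pka=float(entry["pka"]),
        ionization_class=str(entry.get("compound_type", "monoprotic_base")),
        fu_plasma=float(entry["fu"]),
        blood_plasma_ratio=float(entry["b_p"]),
        cl_iv=float(entry["cl_iv"]),
        cl_renal=float(entry["cl_renal"]),
        vss=float(entry["vss"]) if entry.get("vss") is not None else None,
        distribution_mode=str(entry.get("distribution_model", "minimal")),
        binding=binding,
    )
    scheme = MetabolismScheme(
        parent=name,
        pathways=tuple(
            MetabolicPathway(enzyme=str(m["enzyme"]), product=str(m["product"]),
                             percent_contribution=float(m["percent"]))
            for m in entry.get("metabolism", [])
        ),
    )
    return spec, scheme


def load_registry(path=None) -> dict[str, tuple[CompoundSpec, MetabolismScheme]]:
    """Load the compound registry from YAML (built-in file by default)."""
    if path is None:
        text = resources.files("selpbpk.data").joinpath("compounds.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {name: _spec_from_mapping(name, entry) for name, entry in raw.items()}


_REGISTRY_CACHE: dict[str, tuple[CompoundSpec, MetabolismScheme]] | None = None


def builtin_compounds() -> dict[str, CompoundSpec]:
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        _REGISTRY_CACHE = load_registry()
    return {k: v[0] for k, v in _REGISTRY_CACHE.items()}


def builtin_schemes() -> dict[str, MetabolismScheme]:
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        _REGISTRY_CACHE = load_registry()
    return {k: v[1] for k, v in _REGISTRY_CACHE.items()}
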
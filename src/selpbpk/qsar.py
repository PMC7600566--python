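"""Dermal absorption parameter QSARs.

Every partition coefficient, diffusion coefficient and keratin binding
constant of the multi-layer skin model is predicted here from the compound's
physicochemical properties (logP, MW, pKa) and the local pH of each skin
layer.  Any individual parameter may be pinned by an explicit override, which
is recorded with provenance on the assembled parameter set.

Conventions adopted where the published transcriptions are ambiguous:

* dermis:blood — the 0.9993 exponent applies to Kow in both numerator and
  denominator; this is the only reading that reproduces the reference
  estimate 2.44 for logP 2.7.
* molecular radius — sphere-equivalent radius from the molar volume at an
  effective density of 1 g/cm3, expressed in Angstrom.  This reproduces the
  reference stratum-corneum lipid diffusivity within 1%.
* viable-epidermis/dermis diffusivity — the free aqueous diffusivity is
  divided by the binding correction 0.7*(0.68 + 0.32/fu + 0.025*fni*Klip:v).
* keratin off-rate — the printed off-rate expression cannot be reconciled
  with its own reference value; k_off is therefore formula-pluggable with a
  documented default of 0.93 1/h, and k_on = k_off*Kb always.
* sebum diffusivity — the printed Stokes-Einstein-style expression contains
  undefined symbols; the reference estimate 8e-4 cm2/h ships as the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

from .compounds import CompoundSpec, fraction_unionized, log_d
from .errors import ConfigurationError, InputError

AVOGADRO = 6.02214076e23

#: default keratin dissociation rate (1/h) when no off-rate formula is supplied
DEFAULT_KERATIN_KOFF = 0.93
#: default sebum diffusivity (cm2/h)
DEFAULT_D_SEBUM = 8.0e-4

# Assumed (non-QSAR) partition coefficients of the layered skin model
K_DERMIS_VE = 1.0
K_SUBCUTIS_DERMIS = 1.0e-6
K_SUBCUTIS_BLOOD = 1.0


@dataclass(frozen=True)
class DermalParameterSet:
    """All absorption parameters of one compound at one application site.

    Partition coefficients are dimensionless, diffusivities cm2/h, keratin
    rates 1/h, molecular radius Angstrom.  ``provenance`` maps field name to
    "qsar", "assumed" or "override".
    """

    k_lip_vehicle: float
    k_sebum_vehicle: float
    k_sc_ve: float
    k_ve_sebum: float
    k_dermis_ve: float
    k_subcutis_dermis: float
    k_dermis_blood: float
    k_subcutis_blood: float
    d_sc_lipid: float
    d_ve: float
    d_dermis: float
    d_sebum: float
    keratin_kb: float
    keratin_kon: float
    keratin_koff: float
    molecular_radius: float
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        for name in ("k_lip_vehicle", "k_sebum_vehicle", "k_sc_ve", "k_ve_sebum",
                     "k_dermis_ve", "k_dermis_blood", "k_subcutis_blood",
                     "d_sc_lipid", "d_ve", "d_dermis", "d_sebum"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not math.isclose(self.keratin_kon, self.keratin_koff * self.keratin_kb,
                            rel_tol=1e-9):
            raise ConfigurationError(
                "keratin_kon must equal keratin_koff * keratin_kb")


# ---------------------------------------------------------------------------
# Individual QSARs
# ---------------------------------------------------------------------------

def octanol_water(log_p: float) -> float:
    """Octanol:water partition coefficient, Kow = 10^logP."""
    return 10.0 ** log_p


def sc_lipid_vehicle(k_ow: float) -> float:
    """Stratum corneum lipid:vehicle partition coefficient, 1.32*Kow^0.67."""
    if k_ow <= 0:
        raise InputError(f"k_ow must be > 0, got {k_ow}")
    return 1.32 * k_ow ** 0.67


def sebum_vehicle(log_p: float) -> float:
    """Sebum:vehicle partition coefficient, 10^(0.6044*logP + 1.33)."""
    return 10.0 ** (0.6044 * log_p + 1.33)


def dermis_blood(k_ow: float) -> float:
    """Dermis:blood partition coefficient.

    (0.98 + 0.02*Kow^0.9993) / (0.9993 + 0.007*Kow^0.9993); asymptote
    0.02/0.007 = 2.857 for very lipophilic permeants.
    """
    if k_ow <= 0:
        raise InputError(f"k_ow must be > 0, got {k_ow}")
    kp = k_ow ** 0.9993
    return (0.98 + 0.02 * kp) / (0.9993 + 0.007 * kp)


def molecular_radius(molecular_weight: float) -> float:
    """Sphere-equivalent molecular radius in Angstrom at density 1 g/cm3."""
    if molecular_weight <= 0:
        raise InputError("molecular_weight must be > 0")
    volume_cm3 = molecular_weight / AVOGADRO      # molar volume per molecule
    volume_a3 = volume_cm3 * 1.0e24
    return (3.0 * volume_a3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def diffusion_sc_lipid(r_c: float) -> float:
    """Stratum corneum lipid diffusivity (cm2/h) from molecular radius (A)."""
    if r_c <= 0:
        raise InputError("molecular radius must be > 0")
    return 3600.0 * (2.0e-5 * math.exp(-0.46 * r_c ** 2)) + 3600.0 * 3.0e-9


def diffusion_ve_free(molecular_weight: float) -> float:
    """Free aqueous diffusivity in viable epidermis, cm2/s."""
    if molecular_weight <= 0:
        raise InputError("molecular_weight must be > 0")
    return 10.0 ** (-4.38 - 0.207 * molecular_weight ** (1.0 / 3.0))


def binding_correction(fu: float, fni_ve: float, k_lip_vehicle: float) -> float:
    """Divisor accounting for protein/lipid binding in aqueous skin layers."""
    if fu <= 0:
        raise InputError("fu must be > 0")
    return 0.7 * (0.68 + 0.32 / fu + 0.025 * fni_ve * k_lip_vehicle)


def diffusion_ve(molecular_weight: float, fu: float, fni_ve: float,
                 k_lip_vehicle: float) -> float:
    """Viable-epidermis (and dermis) diffusivity, cm2/h.

    3600 * D_free / [0.7*(0.68 + 0.32/fu + 0.025*fni*Klip:v)].
    """
    return 3600.0 * diffusion_ve_free(molecular_weight) / binding_correction(
        fu, fni_ve, k_lip_vehicle)


def keratin_binding(log_d_at_sc_ph: float,
                    koff_formula: Callable[[float], float] | None = None,
                    ) -> tuple[float, float, float]:
    """Keratin binding constants (Kb, k_on 1/h, k_off 1/h).

    log Kb = 1.26 + 0.34*logD at stratum-corneum pH; k_off from the supplied
    formula (default: constant DEFAULT_KERATIN_KOFF); k_on = k_off*Kb always.
    """
    kb = 10.0 ** (1.26 + 0.34 * log_d_at_sc_ph)
    koff = (koff_formula(log_d_at_sc_ph) if koff_formula is not None
            else DEFAULT_KERATIN_KOFF)
    return kb, koff * kb, koff


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_dermal_parameters(compound: CompoundSpec,
                               site_ph: dict | None = None,
                               overrides: dict | None = None,
                               koff_formula: Callable[[float], float] | None = None,
                               ) -> DermalParameterSet:
    """Fill a complete DermalParameterSet from the QSARs.

    ``site_ph`` must provide 'surface' (stratum corneum) and 'viable_epidermis'
    pH; defaults are 6.8 and 7.4.  ``overrides`` pins any field to an explicit
    value (provenance flagged "override"); overriding ``keratin_kb`` alone
    recomputes k_on = k_off*Kb to preserve the detailed-balance identity.
    """
    ph = {"surface": 6.8, "viable_epidermis": 7.4}
    if site_ph:
        ph.update(site_ph)
    for layer in ("surface", "viable_epidermis"):
        if ph.get(layer) is None:
            raise ConfigurationError(f"missing pH for layer '{layer}'")
    overrides = dict(overrides or {})

    k_ow = octanol_water(compound.log_p)
    fni_ve = fraction_unionized(compound.pka, ph["viable_epidermis"],
                                compound.ionization_class)
    values = {
        "k_lip_vehicle": sc_lipid_vehicle(k_ow),
        "k_sebum_vehicle": sebum_vehicle(compound.log_p),
        "k_dermis_blood": dermis_blood(k_ow),
        "molecular_radius": molecular_radius(compound.molecular_weight),
    }
    values["k_ve_sebum"] = values["k_lip_vehicle"] / values["k_sebum_vehicle"]
    # the SC-lipid:VE partition QSAR transcription is unresolved; default to the
    # lipid:vehicle coefficient reduced by the aqueous binding correction
    values["k_sc_ve"] = values["k_lip_vehicle"] / binding_correction(
        compound.fu_plasma, fni_ve, values["k_lip_vehicle"])
    values["d_sc_lipid"] = diffusion_sc_lipid(values["molecular_radius"])
    values["d_ve"] = diffusion_ve(compound.molecular_weight, compound.fu_plasma,
                                  fni_ve, values["k_lip_vehicle"])
    values["d_dermis"] = values["d_ve"]
    values["d_sebum"] = DEFAULT_D_SEBUM
    values["k_dermis_ve"] = K_DERMIS_VE
    values["k_subcutis_dermis"] = K_SUBCUTIS_DERMIS
    values["k_subcutis_blood"] = K_SUBCUTIS_BLOOD

    logd_sc = log_d(compound.log_p, compound.pka, ph["surface"],
                    compound.ionization_class)
    kb, kon, koff = keratin_binding(logd_sc, koff_formula)
    values.update(keratin_kb=kb, keratin_kon=kon, keratin_koff=koff)

    provenance = {name: "qsar" for name in values}
    for name in ("k_dermis_ve", "k_subcutis_dermis", "k_subcutis_blood"):
        provenance[name] = "assumed"
    provenance["d_sebum"] = "assumed"

    unknown = set(overrides) - set(values)
    if unknown:
        raise ConfigurationError(f"unknown override fields: {sorted(unknown)}")
    values.update(overrides)
    for name in overrides:
        provenance[name] = "override"
    # keep k_on = k_off * Kb exact under partial keratin overrides
    if ("keratin_kb" in overrides or "keratin_koff" in overrides) \
            and "keratin_kon" not in overrides:
        values["keratin_kon"] = values["keratin_koff"] * values["keratin_kb"]
    return DermalParameterSet(provenance=provenance, **values)


#: overrides pinning the selegiline parameter set to its reference estimates
SEL_OVERRIDES = {
    "k_sc_ve": 24.8,
    "keratin_kon": 78.8,
    "keratin_koff": 0.93,
    "keratin_kb": 78.8 / 0.93,
    "d_sebum": 8.0e-4,
}


def dermal_parameters_table(compounds: dict[str, CompoundSpec],
                            overrides_by_compound: dict | None = None):
    """One row of DermalParameterSet fields per compound (batch interface)."""
    import pandas as pd

    overrides_by_compound = overrides_by_compound or {}
    rows = []
    for name, spec in compounds.items():
        ps = assemble_dermal_parameters(spec, overrides=overrides_by_compound.get(name))
        row = {f: getattr(ps, f) for f in ps.__dataclass_fields__ if f != "provenance"}
        row["compound"] = name
        rows.append(row)
    return pd.DataFrame(rows).set_index("compound")
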
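"""Tissue:plasma partition coefficients and volume of distribution.

The parent (and any other full-PBPK compound) uses the mechanistic
tissue-composition method for moderate-to-strong monoprotic bases: partition
into tissue water follows ionization (intracellular pH 7.0 vs plasma 7.4),
the ionized species binds to tissue acidic phospholipids with an association
constant back-calculated from blood-cell partitioning (via B/P, fu and
hematocrit), and the neutral species partitions into neutral lipid and
neutral phospholipid.

Minimal-PBPK compounds bypass the prediction and take their steady-state
volume of distribution directly from the compound table.

Because the composition table is a re-implementation (the source simulator's
table is proprietary), predicted Vss carries ~30% uncertainty; a global
``kp_scalar`` calibration knob pins Vss to the compound-table value for
simulation runs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .compounds import CompoundSpec
from .errors import ConfigurationError

PLASMA_PH = 7.4
DEFAULT_HEMATOCRIT = 0.45
#: blood volume as a fraction of body weight (L/kg)
BLOOD_VOLUME_FRAC = 0.0655
REFERENCE_BODY_WEIGHT = 81.0   # kg, adult male reference

_PERFUSION_TISSUES = ("adipose", "bone", "brain", "gut", "heart", "kidney",
                      "liver", "lung", "muscle", "pancreas", "skin", "spleen")


_CSV_CACHE: dict[str, pd.DataFrame] = {}


def _read_package_csv(name: str) -> pd.DataFrame:
    if name not in _CSV_CACHE:
        text = resources.files("selpbpk.data").joinpath(name).read_text()
        _CSV_CACHE[name] = pd.read_csv(io.StringIO(text), comment="#")
    return _CSV_CACHE[name].copy()


def load_tissue_composition() -> pd.DataFrame:
    df = _read_package_csv("tissue_composition.csv").set_index("tissue")
    missing = set(_PERFUSION_TISSUES) - set(df.index)
    if missing:
        raise ConfigurationError(f"composition table missing tissues: {sorted(missing)}")
    return df


def load_reference_physiology() -> pd.DataFrame:
    return _read_package_csv("physiology.csv").set_index("tissue")


@dataclass(frozen=True)
class DispositionModel:
    """Distribution parameters of one compound: full (per-tissue Kp) or minimal."""

    mode: str                                   # {"full", "minimal"}
    vss: float                                  # L/kg
    kp_by_tissue: dict = field(default_factory=dict)
    kp_scalar: float = 1.0

    def kp(self, tissue: str) -> float:
        return self.kp_by_tissue[tissue] * self.kp_scalar


# ---------------------------------------------------------------------------
# Partition-coefficient prediction (moderate-to-strong base class)
# ---------------------------------------------------------------------------

def _ionized_ratio(pka: float, ph: float) -> float:
    return 10.0 ** (pka - ph)


def _neutral_lipid_term(p_ow: float, f_nl: float, f_np: float) -> float:
    return p_ow * f_nl + (0.3 * p_ow + 0.7) * f_np


def acidic_phospholipid_ka(compound: CompoundSpec,
                           composition: pd.DataFrame | None = None,
                           hematocrit: float = DEFAULT_HEMATOCRIT) -> float:
    """Association constant to acidic phospholipids from blood-cell partitioning.

    Kpu_BC = (B/P - (1 - Hct)) / (Hct * fu); the residual of Kpu_BC after
    removing water and neutral-lipid partitioning is attributed to acidic
    phospholipid binding of the ionized base.
    """
    if composition is None:
        composition = load_tissue_composition()
    bc = composition.loc["blood_cells"]
    p_ow = 10.0 ** compound.log_p
    x = 1.0 + _ionized_ratio(compound.pka, PLASMA_PH)
    y_bc = 1.0 + _ionized_ratio(compound.pka, bc["ph_iw"])
    kpu_bc = (compound.blood_plasma_ratio - (1.0 - hematocrit)) / (
        hematocrit * compound.fu_plasma)
    residual = kpu_bc - (y_bc / x) * bc["f_iw"] \
        - _neutral_lipid_term(p_ow, bc["f_nl"], bc["f_np"]) / x
    ka = residual * x / (bc["ap_mg_g"] * _ionized_ratio(compound.pka, bc["ph_iw"]))
    return max(ka, 0.0)


def rodgers_rowland_kp(compound: CompoundSpec, tissue: str,
                       composition: pd.DataFrame | None = None,
                       ka_ap: float | None = None) -> float:
    """Tissue:plasma partition coefficient (Kp) for a monoprotic base."""
    if compound.ionization_class != "monoprotic_base":
        raise ConfigurationError(
            f"unsupported ionization class {compound.ionization_class!r}")
    if composition is None:
        composition = load_tissue_composition()
    if tissue not in composition.index:
        raise ConfigurationError(f"no composition entry for tissue {tissue!r}")
    row = composition.loc[tissue]
    for col in ("f_ew", "f_iw", "f_nl", "f_np", "ap_mg_g", "ph_iw"):
        if pd.isna(row[col]):
            raise ConfigurationError(f"missing composition field {col} for {tissue}")
    if ka_ap is None:
        ka_ap = acidic_phospholipid_ka(compound, composition)
    p_ow = 10.0 ** compound.log_p
    x = 1.0 + _ionized_ratio(compound.pka, PLASMA_PH)
    y = 1.0 + _ionized_ratio(compound.pka, row["ph_iw"])
    kpu = (row["f_ew"]
           + (y / x) * row["f_iw"]
           + ka_ap * row["ap_mg_g"] * _ionized_ratio(compound.pka, row["ph_iw"]) / x
           + _neutral_lipid_term(p_ow, row["f_nl"], row["f_np"]) / x)
    return kpu * compound.fu_plasma


def kp_table(compound: CompoundSpec,
             composition: pd.DataFrame | None = None) -> dict[str, float]:
    """Kp for every perfusion tissue (shared acidic-phospholipid Ka)."""
    if composition is None:
        composition = load_tissue_composition()
    ka = acidic_phospholipid_ka(compound, composition)
    return {t: rodgers_rowland_kp(compound, t, composition, ka_ap=ka)
            for t in _PERFUSION_TISSUES}


def vss_from_kp(kp_by_tissue: dict[str, float],
                tissue_volumes: dict[str, float],
                blood_volume: float, b_p: float,
                body_weight: float = REFERENCE_BODY_WEIGHT) -> float:
    """Steady-state volume of distribution, L/kg, referenced to plasma.

    Vss = [sum_t Kp_t * V_t + B/P * V_blood] / BW.
    """
    total = sum(kp_by_tissue[t] * v for t, v in tissue_volumes.items())
    return (total + b_p * blood_volume) / body_weight


def predicted_vss(compound: CompoundSpec,
                  composition: pd.DataFrame | None = None,
                  physiology: pd.DataFrame | None = None,
                  body_weight: float = REFERENCE_BODY_WEIGHT) -> float:
    """Whole-body Vss (L/kg) from the predicted Kp set and reference volumes."""
    if physiology is None:
        physiology = load_reference_physiology()
    kps = kp_table(compound, composition)
    volumes = {t: physiology.loc[t, "volume_frac_bw"] * body_weight
               for t in _PERFUSION_TISSUES}
    return vss_from_kp(kps, volumes, BLOOD_VOLUME_FRAC * body_weight,
                       compound.blood_plasma_ratio, body_weight)


def build_disposition(compound: CompoundSpec,
                      pin_vss: bool = True) -> DispositionModel:
    """Disposition model per the compound's declared mode.

    Full mode predicts the Kp set and, when ``pin_vss`` and the compound table
    carries a Vss, calibrates ``kp_scalar`` so the whole-body Vss matches that
    value exactly.  Minimal mode takes Vss directly from the compound table.
    """
    if compound.distribution_mode == "minimal":
        if compound.vss is None:
            raise ConfigurationError(
                f"minimal-PBPK compound {compound.name} requires a vss input")
        return DispositionModel(mode="minimal", vss=compound.vss)

    physiology = load_reference_physiology()
    kps = kp_table(compound)
    vss_pred = predicted_vss(compound, physiology=physiology)
    scalar = 1.0
    vss = vss_pred
    if pin_vss and compound.vss is not None:
        # scale the tissue term so total Vss hits the declared value
        blood_term = compound.blood_plasma_ratio * BLOOD_VOLUME_FRAC
        tissue_term = vss_pred - blood_term
        if tissue_term <= 0:
            raise ConfigurationError("predicted tissue distribution is non-positive")
        scalar = (compound.vss - blood_term) / tissue_term
        if scalar <= 0:
            raise ConfigurationError(
                f"cannot pin Vss {compound.vss} below the blood volume term")
        vss = compound.vss
    return DispositionModel(mode="full", vss=vss, kp_by_tissue=kps, kp_scalar=scalar)


def kp_report(compounds: dict[str, CompoundSpec]) -> pd.DataFrame:
    """Kp per compound per tissue (CSV-ready report)."""
    rows = {}
    for name, spec in compounds.items():
        if spec.distribution_mode == "full":
            rows[name] = kp_table(spec)
    return pd.DataFrame(rows).T
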
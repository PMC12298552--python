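"""Virtual-subject physiology for whole-body mAb PBPK models.

Builds per-tissue volumes, sub-compartment volumes (vascular / endosomal /
interstitial), plasma and lymph flows, and endosomal FcRn concentrations for
one virtual adult or pediatric subject.  Reference values for a 70 kg adult
are bundled as a CSV table in the style of published whole-body mAb PBPK
physiologies; pediatric subjects are derived from the same table using an
age-indexed growth table.  FcRn tissue concentrations are deliberately kept
identical between adults and children (no FcRn ontogeny).

Only physiological quantities live here; drug-specific constants are in
:mod:`pedmab.drugs` and are never touched by the scaling functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import ConfigError, RangeError, UnsupportedAgeError

REF_WEIGHT_KG = 70.0
REF_PLASMA_ML = 3126.0
REF_LYMPHNODE_ML = 274.0
#: Default endogenous IgG plasma concentration, μM (~12.8 mg/mL at 150 kDa).
DEFAULT_ENDOGENOUS_IGG_UM = 85.0

TISSUES = (
    "lung", "heart", "kidney", "brain", "muscle", "skin", "adipose",
    "bone", "liver", "spleen", "gut", "pancreas", "thymus", "other",
)


@dataclass(frozen=True)
class TissuePhysiology:
    """One tissue's volumes (mL), flows (mL/day) and FcRn level (μM)."""

    name: str
    V_total: float
    V_vasc: float
    V_endo: float
    V_int: float
    Q: float          # plasma flow, mL/day
    L: float          # lymph flow, mL/day
    FcRn_conc: float  # endosomal FcRn concentration, μM

    def __post_init__(self):
        for f_ in ("V_total", "V_vasc", "V_endo", "V_int", "Q", "L", "FcRn_conc"):
            if getattr(self, f_) <= 0:
                raise RangeError(f"{self.name}.{f_}", getattr(self, f_), "must be > 0")
        if self.V_vasc + self.V_endo + self.V_int > self.V_total * (1 + 1e-9):
            raise RangeError(f"{self.name}.subvolumes",
                             self.V_vasc + self.V_endo + self.V_int,
                             f"exceed V_total={self.V_total}")
        if self.L >= self.Q:
            raise RangeError(f"{self.name}.L", self.L, f"lymph flow must be < plasma flow Q={self.Q}")


@dataclass(frozen=True)
class Demographics:
    age: float      # years
    weight: float   # kg
    sex: str = "male"
    bmi: float | None = None  # kg/m²


@dataclass(frozen=True)
class BodyPhysiology:
    """Whole-body physiological parameter set for one virtual subject."""

    demographics: Demographics
    V_plasma: float      # mL
    V_lymphnode: float   # mL
    tissues: tuple[TissuePhysiology, ...]
    endogenous_IgG_conc: float = DEFAULT_ENDOGENOUS_IGG_UM  # μM

    @property
    def cardiac_plasma_flow(self) -> float:
        """Total plasma flow perfusing the tissues (mL/day); star topology."""
        return float(sum(t.Q for t in self.tissues))

    @property
    def total_lymph_flow(self) -> float:
        return float(sum(t.L for t in self.tissues))

    @property
    def total_tissue_volume(self) -> float:
        return float(sum(t.V_total for t in self.tissues))

    def tissue(self, name: str) -> TissuePhysiology:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "BodyPhysiology":
        if hasattr(source, "read"):
            raw = json.load(source)
        else:
            raw = json.loads(source) if source.lstrip().startswith("{") else json.load(open(source))
        return cls(
            demographics=Demographics(**raw["demographics"]),
            V_plasma=raw["V_plasma"],
            V_lymphnode=raw["V_lymphnode"],
            tissues=tuple(TissuePhysiology(**t) for t in raw["tissues"]),
            endogenous_IgG_conc=raw["endogenous_IgG_conc"],
        )


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("pedmab.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_adult_reference() -> pd.DataFrame:
    """Bundled 70 kg adult reference tissue table."""
    return _load_csv("adult_reference.csv")


def load_growth_reference() -> pd.DataFrame:
    """Bundled age-indexed growth table (median weights, brain maturation)."""
    return _load_csv("growth_reference.csv")


def reference_weight(age: float, sex: str = "male") -> float:
    """Median body weight (kg) at a pediatric age, linearly interpolated."""
    g = load_growth_reference()
    col = "weight_female_kg" if sex.lower().startswith("f") else "weight_male_kg"
    return float(np.interp(age, g["age_years"], g[col]))


def _brain_fraction(age: float) -> float:
    g = load_growth_reference()
    return float(np.interp(age, g["age_years"], g["brain_frac"]))


def _build_tissues(volume_scale: float, flow_scale: float,
                   brain_volume_scale: float | None = None) -> tuple[TissuePhysiology, ...]:
    ref = load_adult_reference()
    out = []
    for row in ref.itertuples(index=False):
        vscale = volume_scale
        if brain_volume_scale is not None and row.tissue == "brain":
            vscale = brain_volume_scale
        V = row.volume_mL * vscale
        out.append(TissuePhysiology(
            name=row.tissue,
            V_total=V,
            V_vasc=V * row.vasc_frac,
            V_endo=V * row.endo_frac,
            V_int=V * row.int_frac,
            Q=row.plasma_flow_mL_day * flow_scale,
            L=row.plasma_flow_mL_day * flow_scale * row.lymph_frac,
            FcRn_conc=row.fcrn_uM,
        ))
    return tuple(out)


def build_adult_physiology(age: float, weight: float, sex: str = "male",
                           bmi: float | None = None,
                           endogenous_igg_um: float = DEFAULT_ENDOGENOUS_IGG_UM) -> BodyPhysiology:
    """Physiology for a virtual adult, linearly scaled to the requested weight.

    Deterministic: identical inputs give identical outputs.  Volumes and
    flows both scale linearly with body weight relative to the bundled
    70 kg reference subject.
    """
    if not (18 <= age <= 90):
        raise RangeError("age", age, "supported adult range is 18-90 years")
    if not (30 <= weight <= 200):
        raise RangeError("weight", weight, "supported adult range is 30-200 kg")
    scale = weight / REF_WEIGHT_KG
    return BodyPhysiology(
        demographics=Demographics(age=age, weight=weight, sex=sex, bmi=bmi),
        V_plasma=REF_PLASMA_ML * scale,
        V_lymphnode=REF_LYMPHNODE_ML * scale,
        tissues=_build_tissues(volume_scale=scale, flow_scale=scale),
        endogenous_IgG_conc=endogenous_igg_um,
    )


def build_pediatric_physiology(age: float, weight: float, sex: str = "male",
                               endogenous_igg_um: float = DEFAULT_ENDOGENOUS_IGG_UM) -> BodyPhysiology:
    """Physiology for a virtual pediatric subject (2 <= age < 18 years).

    Organ volumes and plasma volume scale with body weight; plasma and
    lymph flows scale allometrically (weight^0.75); the brain additionally
    follows an age-indexed maturation fraction since it approaches adult
    size early.  FcRn concentrations are copied from the adult reference
    unchanged (no age-dependent FcRn expression is modeled).
    """
    if age < 2:
        raise UnsupportedAgeError("age", age, "no physiology below 2 years")
    if age >= 18:
        raise RangeError("age", age, "pediatric range is 2-18 years; use build_adult_physiology")
    ref_w = reference_weight(age, sex)
    if not (ref_w / 3 <= weight <= ref_w * 3):
        raise RangeError("weight", weight,
                         f"implausible for age {age} (growth-table reference {ref_w:.1f} kg)")
    vol_scale = weight / REF_WEIGHT_KG
    flow_scale = (weight / REF_WEIGHT_KG) ** 0.75
    brain_scale = _brain_fraction(age)  # relative to adult brain volume
    return BodyPhysiology(
        demographics=Demographics(age=age, weight=weight, sex=sex),
        V_plasma=REF_PLASMA_ML * vol_scale,
        V_lymphnode=REF_LYMPHNODE_ML * vol_scale,
        tissues=_build_tissues(volume_scale=vol_scale, flow_scale=flow_scale,
                               brain_volume_scale=brain_scale),
        endogenous_IgG_conc=endogenous_igg_um,
    )


def build_physiology_for(age: float, weight: float, sex: str = "male") -> BodyPhysiology:
    """Dispatch to the adult or pediatric builder on age."""
    if age < 18:
        return build_pediatric_physiology(age, weight, sex)
    return build_adult_physiology(age, weight, sex)


def reduce_tissues(body: BodyPhysiology, keep: tuple[str, ...]) -> BodyPhysiology:
    """Return a reduced physiology containing only the named tissues.

    Used for small analytically tractable systems; cardiac plasma flow is
    by construction the sum over the retained tissues.
    """
    kept = tuple(t for t in body.tissues if t.name in keep)
    if len(kept) != len(keep):
        missing = set(keep) - {t.name for t in kept}
        raise ConfigError(f"unknown tissues: {sorted(missing)}")
    return replace(body, tissues=kept)


def apply_disease_modifiers(drug, tmdd=None, modifiers: dict | None = None):
    """Apply named fold-change modifiers to drug / target parameters.

    Supported modifier names:

    ``kdeg``
        multiplies the endosomal degradation rate constant of the drug
        (used for inflammatory-disease patients).
    ``target_expression``
        multiplies both the target synthesis rate and the baseline free
        target concentration (pool and flux scale together, preserving
        the steady-state relation baseline = ksyn/kdeg_t).

    Returns fresh copies ``(drug', tmdd')``; the inputs are not mutated.
    """
    modifiers = dict(modifiers or {})
    for name, factor in modifiers.items():
        if factor <= 0:
            raise RangeError(f"modifier[{name}]", factor, "fold-factor must be > 0")
    known = {"kdeg", "target_expression"}
    unknown = set(modifiers) - known
    if unknown:
        raise ConfigError(f"unknown disease modifier(s): {sorted(unknown)}; known: {sorted(known)}")
    new_drug = drug.model_copy(deep=True)
    if "kdeg" in modifiers:
        new_drug = new_drug.model_copy(update={"kdeg": drug.kdeg * modifiers["kdeg"]})
    new_tmdd = None
    if tmdd is not None:
        new_tmdd = tmdd.model_copy(deep=True)
        if "target_expression" in modifiers:
            m = modifiers["target_expression"]
            new_tmdd = new_tmdd.model_copy(update={
                "ksyn": tmdd.ksyn * m,
                "baseline_conc": tmdd.baseline_conc * m,
            })
    elif "target_expression" in modifiers:
        raise ConfigError("target_expression modifier given but no TMDD parameters supplied")
    return new_drug, new_tmdd
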
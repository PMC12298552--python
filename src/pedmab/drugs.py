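"""Drug-specific and target-specific constants, unit conversions, dosing.

The bundled drug library carries the parameter sets for the three reference
antibodies (bevacizumab, infliximab, atezolizumab): the fitted vascular and
lymphatic reflection coefficients, the fitted endosomal degradation rate
constant (with separate healthy / patient values where disease adjustment
applies), shared FcRn binding kinetics at pH 6, and — for bevacizumab only —
the soluble-target (VEGF-A) binding and turnover constants for the TMDD
submodel, again with healthy and patient expression levels.

Internally the simulation engine works in μmol and μmol/mL on a time base of
days; molecular weight converts between mg doses and μmol amounts.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .exceptions import ConfigError, DomainError


class DrugParameters(BaseModel):
    """Drug-specific constants of the whole-body model (Table-style units)."""

    model_config = ConfigDict(frozen=True)

    name: str
    MW: float              # kDa
    sigma_v: float         # vascular reflection coefficient, global
    sigma_l: float         # lymphatic reflection coefficient, global
    kdeg: float            # endosomal degradation of unbound exogenous mAb, 1/day
    kon_fcrn: float = 8000.0   # FcRn association at pH 6, 1/μM/day
    koff_fcrn: float = 500.0   # FcRn dissociation at pH 6, 1/day
    tmdd_enabled: bool = False

    @model_validator(mode="after")
    def _check(self):
        if not (0 <= self.sigma_v < 1):
            raise ValueError(f"sigma_v={self.sigma_v} must be in [0, 1)")
        if not (0 <= self.sigma_l < 1):
            raise ValueError(f"sigma_l={self.sigma_l} must be in [0, 1)")
        if self.MW <= 0:
            raise ValueError("MW must be > 0")
        for f_ in ("kdeg", "kon_fcrn", "koff_fcrn"):
            if getattr(self, f_) <= 0:
                raise ValueError(f"{f_} must be > 0")
        return self


class TMDDParameters(BaseModel):
    """Soluble-target binding and turnover constants (plasma compartment).

    Units: association 1/μM/day; first-order rates 1/day; synthesis
    μmol/mL-plasma/day (plasma density taken as 1 g/mL, so per-gram and
    per-mL synthesis rates are interchangeable); concentrations
    μmol/mL-plasma.
    """

    model_config = ConfigDict(frozen=True)

    kon_t: float           # drug-target association, 1/μM/day
    koff_t: float          # dissociation, 1/day
    kint: float            # complex internalization, 1/day
    ksyn: float            # target synthesis, μmol/mL-plasma/day
    kdeg_t: float          # free-target degradation, 1/day
    baseline_conc: float   # circulating free target, μmol/mL-plasma

    @model_validator(mode="after")
    def _check(self):
        for f_ in ("kon_t", "koff_t", "kint", "ksyn", "kdeg_t", "baseline_conc"):
            if getattr(self, f_) < 0:
                raise ValueError(f"{f_} must be >= 0")
        if self.kdeg_t > 0 and self.baseline_conc > 0:
            implied = self.ksyn / self.kdeg_t
            if abs(implied - self.baseline_conc) > 0.02 * self.baseline_conc:
                raise ValueError(
                    f"steady-state inconsistency: ksyn/kdeg_t={implied:.4g} vs "
                    f"baseline_conc={self.baseline_conc:.4g} (>2% apart)")
        return self


class DoseRegimen(BaseModel):
    """Weight-based or absolute IV dosing with optional cap."""

    model_config = ConfigDict(frozen=True)

    dose_per_kg: Optional[float] = None      # mg/kg
    absolute_dose_mg: Optional[float] = None
    cap_mg: Optional[float] = None
    interval: float = 0.0                    # days between doses
    n_doses: int = 1
    infusion_duration: float = 0.0           # days; 0 = bolus

    @model_validator(mode="after")
    def _check(self):
        if (self.dose_per_kg is None) == (self.absolute_dose_mg is None):
            raise ValueError("exactly one of dose_per_kg / absolute_dose_mg must be set")
        if self.dose_per_kg is not None and self.dose_per_kg < 0:
            raise ValueError("dose_per_kg must be >= 0")
        if self.absolute_dose_mg is not None and self.absolute_dose_mg < 0:
            raise ValueError("absolute_dose_mg must be >= 0")
        if self.cap_mg is not None and self.cap_mg <= 0:
            raise ValueError("cap_mg must be > 0")
        if self.n_doses > 1 and self.interval <= 0:
            raise ValueError("interval must be > 0 when n_doses > 1")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.infusion_duration < 0:
            raise ValueError("infusion_duration must be >= 0")
        return self

    def dose_times(self) -> list[float]:
        return [k * self.interval for k in range(self.n_doses)]


def compute_dose(regimen: DoseRegimen, weight: float) -> float:
    """Administered dose in mg for one administration, cap applied."""
    if weight <= 0:
        raise DomainError(f"weight={weight} must be > 0")
    dose = regimen.absolute_dose_mg if regimen.absolute_dose_mg is not None \
        else regimen.dose_per_kg * weight
    if regimen.cap_mg is not None:
        dose = min(dose, regimen.cap_mg)
    return float(dose)


def mg_to_umol(dose_mg: float, mw_kda: float) -> float:
    """mg of protein → μmol (1 mg of a 149 kDa protein = 1/149 μmol)."""
    if mw_kda <= 0:
        raise DomainError(f"MW={mw_kda} must be > 0")
    if dose_mg < 0:
        raise DomainError(f"dose={dose_mg} must be >= 0")
    return dose_mg / mw_kda


def umol_to_mg(amount_umol: float, mw_kda: float) -> float:
    if mw_kda <= 0:
        raise DomainError(f"MW={mw_kda} must be > 0")
    return amount_umol * mw_kda


class DrugRecord(BaseModel):
    """One drug library entry; healthy/patient variants resolved on demand."""

    model_config = ConfigDict(frozen=True)

    name: str
    mw_kda: float
    sigma_v: float
    sigma_l: float
    kdeg_healthy: float
    kdeg_patient: float
    kon_fcrn: float
    koff_fcrn: float
    tmdd_enabled: bool
    tmdd_healthy: Optional[TMDDParameters] = None
    tmdd_patient: Optional[TMDDParameters] = None

    # Convenience aliases mirroring the published symbols.
    @property
    def sigma_L(self) -> float:
        return self.sigma_l

    def drug_parameters(self, population: str = "healthy") -> DrugParameters:
        kdeg = self.kdeg_healthy if population == "healthy" else self.kdeg_patient
        return DrugParameters(
            name=self.name, MW=self.mw_kda, sigma_v=self.sigma_v,
            sigma_l=self.sigma_l, kdeg=kdeg, kon_fcrn=self.kon_fcrn,
            koff_fcrn=self.koff_fcrn, tmdd_enabled=self.tmdd_enabled)

    def tmdd_parameters(self, population: str = "healthy") -> Optional[TMDDParameters]:
        if not self.tmdd_enabled:
            return None
        return self.tmdd_healthy if population == "healthy" else self.tmdd_patient


def load_drug_library(path=None) -> dict[str, DrugRecord]:
    """Load the bundled (or a user-supplied) drug library JSON file."""
    if path is None:
        raw = json.loads(resources.files("pedmab.data").joinpath("drug_library.json").read_text())
    else:
        with open(path) as fh:
            raw = json.load(fh)
    lib = {}
    for name, entry in raw.items():
        try:
            lib[name] = DrugRecord(name=name, **entry)
        except Exception as exc:  # re-raise with file context
            raise ConfigError(f"invalid drug library entry {name!r}: {exc}") from exc
    return lib


def get_drug(name: str, population: str = "healthy", path=None):
    """Return ``(DrugParameters, TMDDParameters | None)`` for a library drug."""
    lib = load_drug_library(path)
    if name not in lib:
        raise ConfigError(f"unknown drug {name!r}; library has {sorted(lib)}")
    rec = lib[name]
    return rec.drug_parameters(population), rec.tmdd_parameters(population)
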
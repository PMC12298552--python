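"""Synthetic observed-style concentration-time datasets.

Stands in for the digitized clinical profiles the translation workflow is
exercised against.  Each study design mirrors the structure of a published
study (population, demographics, dose arms, sparse IV sampling) and data
are generated by simulating a truth model and multiplying the sampled
concentrations by log-normal proportional residual error:

    C_obs = C_model · exp(ε),   ε ~ N(0, sqrt(ln(1 + CV²)))

so that the geometric CV of the observations equals the design CV.  CV = 0
returns exact model values.  All randomness flows through the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .drugs import DoseRegimen, DrugParameters, TMDDParameters, get_drug
from .engine import EngineOptions, assemble_model, simulate
from .exceptions import DesignError
from .physiology import build_physiology_for, reference_weight

POPULATIONS = ("healthy-adult", "adult-patient", "pediatric-patient")

#: observations are truncated below this floor (μg/mL)
CONC_FLOOR = 1e-6


class Arm(BaseModel):
    """One dose arm: a virtual representative subject plus a regimen."""

    model_config = ConfigDict(frozen=True)

    label: str
    age: float
    weight: float
    sex: str = "male"
    regimen: DoseRegimen


class StudyDesign(BaseModel):
    model_config = ConfigDict(frozen=True)

    study_id: str
    population: str
    arms: tuple[Arm, ...]
    sampling_times: tuple[float, ...]   # days
    residual_cv: float = 0.2            # proportional log-normal CV
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.population not in POPULATIONS:
            raise ValueError(f"population must be one of {POPULATIONS}")
        t = np.asarray(self.sampling_times)
        if t.size == 0 or t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing, first >= 0")
        if self.residual_cv < 0:
            raise ValueError("residual CV must be >= 0")
        if not self.arms:
            raise ValueError("need at least one arm")
        return self


@dataclass
class ObservedDataset:
    """Generated study data plus full provenance (truth parameters, seed)."""

    study_id: str
    design: StudyDesign
    records: pd.DataFrame      # columns: arm, time_days, conc_ug_per_ml
    provenance: dict = field(default_factory=dict)

    def arm_profile(self, label: str):
        sub = self.records[self.records["arm"] == label]
        return sub["time_days"].to_numpy(), sub["conc_ug_per_ml"].to_numpy()


def generate_study(design: StudyDesign, drug: DrugParameters,
                   tmdd: Optional[TMDDParameters] = None,
                   options: Optional[EngineOptions] = None,
                   t_end: Optional[float] = None) -> ObservedDataset:
    """Simulate the truth model for every arm and add residual error."""
    times = np.asarray(design.sampling_times, dtype=float)
    horizon = t_end if t_end is not None else float(times.max())
    if times.max() > horizon:
        raise DesignError(f"sampling time {times.max()} beyond horizon {horizon}")
    rng = np.random.default_rng(design.seed)
    sigma = float(np.sqrt(np.log(1 + design.residual_cv ** 2)))
    rows = []
    for arm in design.arms:
        phys = build_physiology_for(arm.age, arm.weight, arm.sex)
        model = assemble_model(phys, drug, tmdd, options)
        res = simulate(model, arm.regimen, weight=arm.weight, t_end=horizon,
                       t_eval=times)
        sim = np.interp(times, res.t, res.cp_ug_ml)
        eps = rng.normal(0.0, sigma, size=times.size) if sigma > 0 else np.zeros(times.size)
        obs = np.maximum(sim * np.exp(eps), CONC_FLOOR)
        for ti, ci in zip(times, obs):
            rows.append({"arm": arm.label, "time_days": ti, "conc_ug_per_ml": ci})
    records = pd.DataFrame(rows)
    prov = {
        "seed": design.seed,
        "residual_cv": design.residual_cv,
        "truth_drug": drug.model_dump(),
        "truth_tmdd": tmdd.model_dump() if tmdd is not None else None,
    }
    return ObservedDataset(study_id=design.study_id, design=design,
                           records=records, provenance=prov)


# ---------------------------------------------------------------------------
# fixture library mirroring the reference study panel
# ---------------------------------------------------------------------------

#: dense-early / sparse-late single-dose schedule (days)
SINGLE_DOSE_TIMES = (0.042, 0.25, 1, 2, 7, 14, 28, 56, 84)
#: multi-dose (0/14/42 d) schedule with peri-dose and trough samples
MULTI_DOSE_TIMES = (0.083, 1, 7, 13.9, 14.083, 28, 41.9, 42.083, 56, 70, 84, 98)
#: q3w multi-dose schedule
Q3W_TIMES = (0.083, 1, 7, 20.9, 21.083, 35, 41.9, 42.083, 56, 63)
ATE_SINGLE_TIMES = (0.042, 0.5, 1, 2, 7, 14, 21, 28, 42, 63)


def _single(dose):
    return DoseRegimen(dose_per_kg=dose)


def _q14x3(dose, cap=None):
    return DoseRegimen(dose_per_kg=dose, cap_mg=cap, interval=14.0, n_doses=3,
                       infusion_duration=0.083)


def _q21x3(dose, cap=None):
    return DoseRegimen(dose_per_kg=dose, cap_mg=cap, interval=21.0, n_doses=3,
                       infusion_duration=0.042)


def fixture_library(base_seed: int = 0, residual_cv: float = 0.2) -> dict[str, StudyDesign]:
    """The full panel of study designs mirroring the reference studies.

    9 bevacizumab studies (6 healthy-adult, 2 adult-patient, 1 pediatric),
    12 infliximab studies (2 healthy, 8 patient, 2 pediatric) and
    2 atezolizumab studies (adult-patient with five dose strengths;
    pediatric 15 mg/kg capped at 1200 mg).  Seeds are derived
    deterministically from ``base_seed``.
    """
    designs: list[StudyDesign] = []

    def D(study_id, population, arms, times):
        designs.append(StudyDesign(
            study_id=study_id, population=population, arms=tuple(arms),
            sampling_times=times, residual_cv=residual_cv,
            seed=base_seed + 97 * len(designs)))

    def arm(label, age, weight, regimen, sex="male"):
        return Arm(label=label, age=age, weight=weight, sex=sex, regimen=regimen)

    # --- bevacizumab -----------------------------------------------------
    D("Bev.Ad.H.1", "healthy-adult", [arm("1mgkg", 27.6, 70, _single(1.0))], SINGLE_DOSE_TIMES)
    D("Bev.Ad.H.2", "healthy-adult", [arm("1mgkg", 27.0, 70, _single(1.0))], SINGLE_DOSE_TIMES)
    D("Bev.Ad.H.3", "healthy-adult", [arm("1mgkg", 31.0, 72, _single(1.0))], SINGLE_DOSE_TIMES)
    D("Bev.Ad.H.4", "healthy-adult", [arm("1mgkg", 23.0, 71, _single(1.0))], SINGLE_DOSE_TIMES)
    D("Bev.Ad.H.5", "healthy-adult", [arm("3mgkg", 39.5, 74, _single(3.0))], SINGLE_DOSE_TIMES)
    D("Bev.Ad.H.6", "healthy-adult", [arm("3mgkg", 39.8, 73, _single(3.0))], SINGLE_DOSE_TIMES)
    D("Bev.Ad.P.1", "adult-patient", [arm("10mgkg", 56.0, 72, _single(10.0))], SINGLE_DOSE_TIMES)
    D("Bev.Ad.P.2", "adult-patient",
      [arm(f"{d}mgkg", 51.0, 70, _single(d)) for d in (0.1, 1.0, 3.0, 10.0)],
      SINGLE_DOSE_TIMES)
    D("Bev.Ped.P", "pediatric-patient",
      [arm("5mgkg", 13.0, 53.65, _single(5.0)), arm("15mgkg", 13.0, 53.65, _single(15.0))],
      SINGLE_DOSE_TIMES)

    # --- infliximab ------------------------------------------------------
    D("Inf.Ad.H.1", "healthy-adult", [arm("5mgkg", 30.0, 70, _single(5.0))], SINGLE_DOSE_TIMES)
    D("Inf.Ad.H.2", "healthy-adult", [arm("5mgkg", 28.0, 72, _single(5.0))], SINGLE_DOSE_TIMES)
    for k, (age, wt, dose) in enumerate(
            [(35, 68, 5.0), (42, 75, 5.0), (50, 80, 5.0), (55, 65, 5.0),
             (38, 70, 3.0), (46, 78, 10.0)], start=1):
        D(f"Inf.Ad.P.{k}", "adult-patient",
          [arm(f"{dose}mgkg", age, wt, _q14x3(dose))], MULTI_DOSE_TIMES)
    D("Inf.Ad.P.7", "adult-patient", [arm("5mgkg", 44.0, 72, _single(5.0))], SINGLE_DOSE_TIMES)
    D("Inf.Ad.P.8", "adult-patient", [arm("10mgkg", 52.0, 74, _single(10.0))], SINGLE_DOSE_TIMES)
    D("Inf.Ped.P.1", "pediatric-patient", [arm("5mgkg", 13.0, 42.0, _q14x3(5.0))],
      MULTI_DOSE_TIMES)
    D("Inf.Ped.P.2", "pediatric-patient",
      [arm("4y-5mgkg", 4.0, reference_weight(4), _q14x3(5.0)),
       arm("10y-10mgkg", 10.0, reference_weight(10), _q14x3(10.0)),
       arm("16y-18mgkg", 16.0, reference_weight(16), _q14x3(18.0))],
      MULTI_DOSE_TIMES)

    # --- atezolizumab ----------------------------------------------------
    D("Ate.Ad.P", "adult-patient",
      [arm(f"{d}mgkg", 63.0, 75, _single(d)) for d in (1.0, 3.0, 10.0, 15.0, 20.0)],
      ATE_SINGLE_TIMES)
    D("Ate.Ped.P", "pediatric-patient",
      [arm(f"{int(a)}y", a, reference_weight(a), _q21x3(15.0, cap=1200.0))
       for a in (2.0, 6.0, 10.0, 16.0)],
      Q3W_TIMES)

    return {d.study_id: d for d in designs}


DRUG_PREFIX = {"Bev": "bevacizumab", "Inf": "infliximab", "Ate": "atezolizumab"}


def truth_parameters(design: StudyDesign):
    """Truth (drug, tmdd) used to generate a given study: healthy studies use
    the healthy parameter set, patient and pediatric-patient studies the
    disease-adjusted one."""
    drug_name = DRUG_PREFIX[design.study_id.split(".")[0]]
    population = "healthy" if design.population == "healthy-adult" else "patient"
    return get_drug(drug_name, population)


def generate_drug_datasets(drug_name: str, base_seed: int = 0,
                           residual_cv: float = 0.2,
                           options: Optional[EngineOptions] = None) -> dict[str, ObservedDataset]:
    """Generate all fixture datasets for one drug at the truth parameters."""
    prefix = {v: k for k, v in DRUG_PREFIX.items()}[drug_name]
    out = {}
    for sid, design in fixture_library(base_seed, residual_cv).items():
        if not sid.startswith(prefix):
            continue
        drug, tmdd = truth_parameters(design)
        out[sid] = generate_study(design, drug, tmdd, options)
    return out
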
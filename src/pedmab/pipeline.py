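"""Adult-to-pediatric translation workflow.

Stages, in order:

1. **development** — fit the three drug-specific parameters (σ_v, σ_L,
   kdeg) on the adult development datasets;
2. **adult validation** — simulate the external adult datasets with the
   fitted (and, for patient studies, disease-adjusted) parameters and
   compare;
3. **disease adjustment** — apply the configured fold-change modifiers
   (e.g. ×1.5 kdeg for inflammatory disease, ×2 target expression for
   cancer patients);
4. **pediatric prediction** — swap in pediatric physiologies, keep every
   drug-specific parameter fixed, simulate, and compare against the
   pediatric datasets.

A drug with no healthy-adult data (the atezolizumab pattern) is developed
directly on adult-patient data; stage 3 is then an identity.

Acceptability is operationalized as AAFE <= 2 and all Cmax/AUC fold errors
<= 2 (the conventional PBPK two-fold criterion); the threshold is
configurable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .calibration import DEFAULT_START, FitResult, fit_drug_parameters
from .drugs import compute_dose, get_drug, load_drug_library
from .engine import EngineOptions, SimulationResult, assemble_model, simulate
from .exceptions import ConfigError, DomainError
from .nca import aafe, fold_error, nca
from .physiology import apply_disease_modifiers, build_physiology_for
from .synthetic import ObservedDataset


class TranslationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    drug_name: str
    development_ids: tuple[str, ...]
    validation_ids: tuple[str, ...] = ()
    pediatric_ids: tuple[str, ...] = ()
    disease_modifiers: dict[str, float] = {}
    acceptance_fold: float = 2.0
    fit_initial: tuple[float, float, float] = DEFAULT_START
    fit_max_evals: int = 300

    @model_validator(mode="after")
    def _check(self):
        overlap = set(self.development_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"development and validation sets overlap: {sorted(overlap)}")
        if self.acceptance_fold <= 1:
            raise ValueError("acceptance_fold must be > 1")
        if not self.development_ids:
            raise ValueError("need at least one development dataset")
        return self


@dataclass
class ProfileComparison:
    study_id: str
    arm: str
    n_points: int
    aafe: float
    fold_cmax: Optional[float]
    fold_auc: Optional[float]
    fold_thalf: Optional[float]
    passed: bool


@dataclass
class StageResult:
    name: str
    executed: bool
    passed: Optional[bool]
    entries: list = field(default_factory=list)


@dataclass
class ValidationReport:
    drug_name: str
    threshold: float
    fitted: dict
    stages: list
    audit: dict
    log: list

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "ValidationReport":
        raw = json.loads(source if isinstance(source, str) and source.lstrip().startswith("{")
                         else open(source).read())
        stages = [StageResult(name=s["name"], executed=s["executed"], passed=s["passed"],
                              entries=[ProfileComparison(**e) for e in s["entries"]])
                  for s in raw["stages"]]
        return cls(drug_name=raw["drug_name"], threshold=raw["threshold"],
                   fitted=raw["fitted"], stages=stages, audit=raw["audit"],
                   log=raw["log"])

    def stage(self, name: str) -> StageResult:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def pediatric_aafe(self) -> list[float]:
        return [e.aafe for e in self.stage("pediatric_prediction").entries]


def compare_profiles(observed, simulated: SimulationResult,
                     dose_mg: Optional[float] = None,
                     weight: Optional[float] = None) -> dict:
    """Compare one observed profile against a simulation.

    ``observed`` is a ``(times, concentrations)`` pair (days, μg/mL).  The
    simulated profile is interpolated log-linearly in concentration at the
    observed times; AAFE summarizes point-wise agreement and NCA metrics
    are compared as symmetric fold errors (None where not estimable).
    """
    t_obs = np.asarray(observed[0], dtype=float)
    c_obs = np.asarray(observed[1], dtype=float)
    if t_obs.size == 0:
        raise DomainError("empty observed profile")
    if t_obs.min() < simulated.t.min() - 1e-9 or t_obs.max() > simulated.t.max() + 1e-9:
        raise DomainError("observed times outside the simulated horizon")
    pos = simulated.cp_ug_ml > 0
    sim_at_obs = np.exp(np.interp(t_obs, simulated.t[pos],
                                  np.log(simulated.cp_ug_ml[pos])))
    out = {"aafe": aafe(c_obs, sim_at_obs), "n_points": int(t_obs.size),
           "fold_cmax": None, "fold_auc": None, "fold_thalf": None}
    out["fold_cmax"] = fold_error(float(c_obs.max()), float(sim_at_obs.max()))
    if t_obs.size >= 3:
        m_obs = nca(t_obs, c_obs, dose_mg=dose_mg, weight=weight)
        m_sim = nca(t_obs, sim_at_obs, dose_mg=dose_mg, weight=weight)
        if m_obs.auc_0_t > 0 and m_sim.auc_0_t > 0:
            out["fold_auc"] = fold_error(m_obs.auc_0_t, m_sim.auc_0_t)
        if m_obs.t_half and m_sim.t_half:
            out["fold_thalf"] = fold_error(m_obs.t_half, m_sim.t_half)
    return out


def _simulate_arm(drug, tmdd, arm, t_obs, options):
    phys = build_physiology_for(arm.age, arm.weight, arm.sex)
    model = assemble_model(phys, drug, tmdd, options)
    t_end = float(np.max(t_obs))
    grid = np.unique(np.concatenate([np.linspace(0.0, t_end, 201), t_obs]))
    res = simulate(model, arm.regimen, weight=arm.weight, t_end=t_end, t_eval=grid)
    return res, phys


def _compare_dataset(ds: ObservedDataset, drug, tmdd, threshold, options):
    entries = []
    for arm in ds.design.arms:
        t_obs, c_obs = ds.arm_profile(arm.label)
        res, _ = _simulate_arm(drug, tmdd, arm, t_obs, options)
        dose_mg = compute_dose(arm.regimen, arm.weight)
        cmp_ = compare_profiles((t_obs, c_obs), res, dose_mg=dose_mg,
                                weight=arm.weight)
        folds = [v for v in (cmp_["fold_cmax"], cmp_["fold_auc"]) if v is not None]
        passed = cmp_["aafe"] <= threshold and all(f <= threshold for f in folds)
        entries.append(ProfileComparison(
            study_id=ds.study_id, arm=arm.label, n_points=cmp_["n_points"],
            aafe=cmp_["aafe"], fold_cmax=cmp_["fold_cmax"],
            fold_auc=cmp_["fold_auc"], fold_thalf=cmp_["fold_thalf"],
            passed=passed))
    return entries


def run_translation(config: TranslationConfig,
                    datasets: dict[str, ObservedDataset],
                    options: Optional[EngineOptions] = None) -> ValidationReport:
    """Execute the full translation workflow and emit a validation report."""
    log: list[str] = []
    needed = (list(config.development_ids) + list(config.validation_ids)
              + list(config.pediatric_ids))
    missing = [sid for sid in needed if sid not in datasets]
    if missing:
        raise ConfigError(f"missing datasets: {missing}")
    seen = set()
    for sid in needed:
        if sid in seen:
            raise ConfigError(f"dataset {sid} referenced more than once")
        seen.add(sid)

    lib = load_drug_library()
    if config.drug_name not in lib:
        raise ConfigError(f"unknown drug {config.drug_name!r}")
    rec = lib[config.drug_name]

    dev_sets = [datasets[sid] for sid in config.development_ids]
    dev_pops = {d.design.population for d in dev_sets}
    if len(dev_pops) > 1:
        raise ConfigError(f"development datasets span populations {sorted(dev_pops)}")
    dev_pop = dev_pops.pop()
    dev_is_patient = dev_pop != "healthy-adult"
    pop_key = "patient" if dev_is_patient else "healthy"
    base_drug = rec.drug_parameters(pop_key)
    base_tmdd = rec.tmdd_parameters(pop_key)
    if dev_is_patient:
        log.append(f"no healthy-adult data: developing directly on {dev_pop} data")

    stages: list[StageResult] = []

    # --- stage 1: development fit ---------------------------------------
    fit = fit_drug_parameters(dev_sets, base_drug, base_tmdd,
                              initial=config.fit_initial,
                              max_evals=config.fit_max_evals,
                              options=options)
    fitted_drug = fit.as_drug(base_drug)
    log.append(f"development fit: sigma_v={fit.sigma_v:.4f} "
               f"sigma_l={fit.sigma_l:.4f} kdeg={fit.kdeg:.4g} "
               f"(SSE={fit.objective_value:.4g}, {fit.n_eval} evals)")
    dev_entries = []
    for ds in dev_sets:
        dev_entries += _compare_dataset(ds, fitted_drug, base_tmdd,
                                        config.acceptance_fold, options)
    stage_dev = StageResult("development", True,
                            all(e.passed for e in dev_entries), dev_entries)
    stages.append(stage_dev)

    # --- stage 3 is computed up front so validation can use patient params
    if dev_is_patient or not config.disease_modifiers:
        patient_drug, patient_tmdd = fitted_drug, base_tmdd
    else:
        patient_drug, patient_tmdd = apply_disease_modifiers(
            fitted_drug, base_tmdd, config.disease_modifiers)
        log.append(f"disease adjustment: {dict(config.disease_modifiers)} -> "
                   f"kdeg={patient_drug.kdeg:.4g}")

    # --- stage 2: adult external validation -----------------------------
    val_stage = StageResult("adult_validation", False, None)
    ped_stage = StageResult("pediatric_prediction", False, None)
    stages += [val_stage, ped_stage]

    if stage_dev.passed:
        entries = []
        for sid in config.validation_ids:
            ds = datasets[sid]
            if ds.design.population == "healthy-adult":
                drug_v, tmdd_v = fitted_drug, base_tmdd
            else:
                drug_v, tmdd_v = patient_drug, patient_tmdd
            entries += _compare_dataset(ds, drug_v, tmdd_v,
                                        config.acceptance_fold, options)
        val_stage.executed = True
        val_stage.entries = entries
        val_stage.passed = all(e.passed for e in entries) if entries else True
    else:
        log.append("development stage failed: later stages skipped")

    # --- stage 4: pediatric prediction ----------------------------------
    if val_stage.executed and val_stage.passed:
        entries = []
        for sid in config.pediatric_ids:
            entries += _compare_dataset(datasets[sid], patient_drug,
                                        patient_tmdd, config.acceptance_fold,
                                        options)
        ped_stage.executed = True
        ped_stage.entries = entries
        ped_stage.passed = all(e.passed for e in entries) if entries else True
    elif val_stage.executed:
        log.append("adult validation failed: pediatric stage skipped")

    kdeg_factor = 1.0 if dev_is_patient else config.disease_modifiers.get("kdeg", 1.0)
    audit = {
        "adult_fitted": {"sigma_v": fit.sigma_v, "sigma_l": fit.sigma_l,
                         "kdeg": fit.kdeg},
        "pediatric_drug": {"sigma_v": patient_drug.sigma_v,
                           "sigma_l": patient_drug.sigma_l,
                           "kdeg": patient_drug.kdeg},
        "modifiers": dict(config.disease_modifiers) if not dev_is_patient else {},
        "drug_params_held_constant": (
            patient_drug.sigma_v == fit.sigma_v
            and patient_drug.sigma_l == fit.sigma_l
            and abs(patient_drug.kdeg - fit.kdeg * kdeg_factor) <= 1e-9 * fit.kdeg),
    }

    return ValidationReport(drug_name=config.drug_name,
                            threshold=config.acceptance_fold,
                            fitted={"sigma_v": fit.sigma_v, "sigma_l": fit.sigma_l,
                                    "kdeg": fit.kdeg,
                                    "objective": fit.objective_value,
                                    "converged": fit.converged,
                                    "n_eval": fit.n_eval,
                                    "at_bound": fit.at_bound},
                            stages=[s for s in stages], audit=audit, log=log)
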
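"""Shared fixtures.

Heavy computations (parameter-recovery fits, the noisy-fit replication
study, end-to-end translation runs, the fixture simulation sweep) are
session-scoped so that unit tests and the acceptance suite share them.
All seeds are fixed here; the suite is fully deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from pedmab.calibration import fit_drug_parameters
from pedmab.drugs import get_drug
from pedmab.engine import assemble_model, simulate
from pedmab.physiology import build_adult_physiology, build_physiology_for
from pedmab.pipeline import TranslationConfig, run_translation
from pedmab.synthetic import (fixture_library, generate_drug_datasets,
                              generate_study, truth_parameters)

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")

NOISY_FIT_SEEDS = tuple(range(1000, 1005))
PIPELINE_SEED = 1

TRUTHS = {
    "bevacizumab": {"study": "Bev.Ad.H.1", "sigma_v": 0.99, "sigma_l": 0.63, "kdeg": 1.24e4},
    "infliximab": {"study": "Inf.Ad.H.1", "sigma_v": 0.99, "sigma_l": 0.60, "kdeg": 1.34e4},
    "atezolizumab": {"study": "Ate.Ad.P", "sigma_v": 0.99, "sigma_l": 0.29, "kdeg": 1.8e4},
}


@pytest.fixture(scope="session")
def adult_phys():
    return build_adult_physiology(30.0, 70.0, "male")


@pytest.fixture(scope="session")
def bev_healthy():
    return get_drug("bevacizumab", "healthy")


@pytest.fixture(scope="session")
def inf_healthy():
    return get_drug("infliximab", "healthy")


@pytest.fixture(scope="session")
def recovery_fits():
    """Noise-free parameter recovery for each drug's truth vector."""
    out = {}
    for drug_name, truth in TRUTHS.items():
        designs = fixture_library(residual_cv=0.0)
        design = designs[truth["study"]]
        drug, tmdd = truth_parameters(design)
        ds = generate_study(design, drug, tmdd)
        out[drug_name] = fit_drug_parameters([ds], drug, tmdd, max_evals=300)
    return out


@pytest.fixture(scope="session")
def noisy_kdeg_fits():
    """Five replicated infliximab fits on 20%-CV data, different noise seeds."""
    kdegs = []
    for seed in NOISY_FIT_SEEDS:
        designs = fixture_library(base_seed=seed, residual_cv=0.2)
        design = designs["Inf.Ad.H.1"]
        drug, tmdd = truth_parameters(design)
        ds = generate_study(design, drug, tmdd)
        fit = fit_drug_parameters([ds], drug, tmdd, max_evals=200)
        kdegs.append(fit.kdeg)
    return kdegs


BEV_CONFIG = TranslationConfig(
    drug_name="bevacizumab",
    development_ids=("Bev.Ad.H.1",),
    validation_ids=("Bev.Ad.H.2", "Bev.Ad.H.3", "Bev.Ad.H.4", "Bev.Ad.H.5",
                    "Bev.Ad.H.6", "Bev.Ad.P.1", "Bev.Ad.P.2"),
    pediatric_ids=("Bev.Ped.P",),
    disease_modifiers={"target_expression": 2.0},
)


@pytest.fixture(scope="session")
def bev_pipeline_cv20():
    datasets = generate_drug_datasets("bevacizumab", base_seed=PIPELINE_SEED,
                                      residual_cv=0.2)
    return run_translation(BEV_CONFIG, datasets)


@pytest.fixture(scope="session")
def bev_pipeline_cv0():
    datasets = generate_drug_datasets("bevacizumab", base_seed=PIPELINE_SEED,
                                      residual_cv=0.0)
    return run_translation(BEV_CONFIG, datasets)


@pytest.fixture(scope="session")
def fixture_sims():
    """One truth-model simulation per fixture arm, at default solver settings."""
    sims = []
    for sid, design in fixture_library().items():
        drug, tmdd = truth_parameters(design)
        horizon = float(max(design.sampling_times))
        for arm in design.arms:
            phys = build_physiology_for(arm.age, arm.weight, arm.sex)
            model = assemble_model(phys, drug, tmdd)
            res = simulate(model, arm.regimen, weight=arm.weight, t_end=horizon)
            sims.append((sid, arm.label, res))
    return sims
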
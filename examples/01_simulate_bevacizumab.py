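"""Simulate a single IV bolus of bevacizumab in a healthy adult.

Builds a 70 kg adult physiology, assembles the whole-body model with the
target (VEGF-A) submodel enabled, integrates 84 days, and summarizes the
plasma profile with non-compartmental metrics.
"""

import numpy as np

from pedmab import DoseRegimen, assemble_model, build_adult_physiology, nca, simulate
from pedmab.drugs import get_drug

phys = build_adult_physiology(age=30, weight=70, sex="male")
drug, tmdd = get_drug("bevacizumab", "healthy")
model = assemble_model(phys, drug, tmdd)

res = simulate(model, DoseRegimen(dose_per_kg=5.0), t_end=84.0)
metrics = nca(res.t, res.cp_ug_ml, dose_mg=350.0, weight=70.0)

print(f"states integrated      : {model.n_states}")
print(f"Cmax                   : {metrics.cmax:.1f} ug/mL "
      "(initial distribution is essentially the plasma volume)")
print(f"AUC(0-84d)             : {metrics.auc_0_t:.0f} ug*day/mL")
print(f"terminal half-life     : {metrics.t_half:.1f} days "
      "(week-scale persistence from FcRn salvage)")
print(f"clearance              : {metrics.clearance:.2f} mL/day/kg")
print(f"mass-balance residual  : {res.mass_balance_residual().max():.2e} "
      "(dose fully accounted for by body + catabolized ledgers)")
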
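# Methods

`pedmab` implements a whole-body physiologically based pharmacokinetic (PBPK)
model for intravenously administered therapeutic monoclonal antibodies
(mAbs), together with the workflow that calibrates it on adult data and
re-parameterizes it with pediatric physiology to predict exposure in
children. This note records the model, its assumptions, the parameter
choices that matter, and the numerical decisions, so that results can be
interpreted and reproduced without reading the source.

## Model structure

A central plasma pool perfuses 14 tissues (lung, heart, kidney, brain,
muscle, skin, adipose, bone, liver, spleen, gut, pancreas, thymus, other) in
parallel (star topology). Each tissue is divided into vascular, endosomal,
and interstitial sub-spaces. For tissue *i* with plasma flow *Q_i*, lymph
flow *L_i* and sub-volumes *V_v*, *V_e*, *V_int*, the drug concentrations
obey (units: μmol/mL, mL, mL/day, days):

```
V_v  dCv/dt  = Q_i Cp − (Q_i − L_i) Cv − (1−σ_v) L_i Cv − k_up V_e Cv + FR k_rec V_e Cb
V_int dCi/dt = (1−σ_v) L_i Cv − (1−σ_L) L_i Ci − k_up V_e Ci + (1−FR) k_rec V_e Cb
     dCe/dt  = k_up (Cv + Ci) − kon·Ce·R_free + koff·Cb − kdeg·Ce
     dCb/dt  = kon·Ce·R_free − koff·Cb − k_rec·Cb,     R_free = FcRn − Cb_drug − Cb_IgG
```

Convective extravasation is attenuated by the vascular reflection
coefficient σ_v and lymphatic drainage by σ_L (one global value of each per
drug — these are the fitted quantities, so tissue-specific values would not
be identifiable). Pinocytosis moves drug from both the vascular and
interstitial spaces into the endosome at `k_up` (1/day referenced to
endosomal volume). In the acidified endosome the drug either binds free
FcRn with the pH-6 kinetics (kon 8000 1/μM/day, koff 500 1/day; Kd
0.0625 μM) or is degraded at the drug-specific rate `kdeg`. Bound drug is
recycled intact at `k_rec`, a fraction `FR` to the vascular side and the
rest to the interstitium; pH-dependent release at the cell surface is
collapsed into this single recycling step (no explicit pH-7.4 binding
state). All tissue lymph collects in a lymph-node compartment that drains
to plasma at the total lymph flow.

Endogenous IgG circulates through the identical transport/FcRn equations
with its own constants (σ_v 0.95, σ_L 0.20, kdeg 1.2e4 1/day, same FcRn
kinetics) and competes with the drug for FcRn capacity. Its synthesis rate
is solved at model-build time so that an 85 μM plasma level (≈12.8 mg/mL)
is exactly stationary; every simulation starts from that baseline.

Optional target-mediated drug disposition (TMDD) places a soluble target in
the plasma pool only:

```
dT/dt  = ksyn − kdeg_t·T − kon_t·Cp·T + koff_t·AT
dAT/dt = kon_t·Cp·T − koff_t·AT − kint·AT
```

with the free target initialized at its zero-dose steady state
`ksyn/kdeg_t`. Among the three bundled drugs only bevacizumab carries a
TMDD block (soluble VEGF-A); infliximab and atezolizumab are linear over
their clinical dose ranges. The tabulated "complex degradation" constant
0.173 1/day is interpreted as the free-target degradation rate `kdeg_t`,
because synthesis/0.173 reproduces the published healthy and patient
expression levels exactly; the complex is eliminated by internalization at
`kint` = 1 1/day. Two cumulative ledgers (drug catabolized + complex
internalized; endogenous IgG catabolized) close the mass balance.

## Parameters

Drug-specific (per drug, from the bundled library; healthy/patient variants
where disease adjustment applies):

| parameter | bevacizumab | infliximab | atezolizumab | role |
|---|---|---|---|---|
| MW (kDa) | 149 | 149.1 | 145 | mg ↔ μmol |
| σ_v | 0.99 | 0.99 | 0.99 | vascular reflection (fitted) |
| σ_L | 0.63 | 0.60 | 0.29 | lymphatic reflection (fitted) |
| kdeg (1/day) | 1.24e4 | 1.34e4 / 2.00e4 | 1.8e4 | endosomal degradation (fitted) |
| TMDD | yes | no | no | |

VEGF-A block (bevacizumab): kon 30 1/μM/day, koff 0.006 1/day, kint 1
1/day, kdeg_t 0.173 1/day, synthesis 0.34e-6 (healthy) / 0.67e-6 (patient)
μmol/mL-plasma/day, baseline 1.96e-6 / 3.86e-6 μmol/mL-plasma (plasma
density taken as 1 g/mL, so per-gram and per-mL synthesis units are
interchangeable).

Machinery constants (not drug-specific, not fitted): `k_up` = 2.0 1/day,
`k_rec` = 100 1/day, `FR` = 0.715. `k_rec` must be commensurate with the
pH-6 koff (500 1/day) for FcRn binding to rescue a meaningful fraction of
endosomal antibody: the per-binding recycling probability is
k_rec/(k_rec+koff) ≈ 0.17, which combined with the binding/degradation
competition yields ~80–90% salvage, week-scale terminal half-lives
(~20–33 days across the three drugs at their fitted kdeg values),
plasma clearances of ~1.9–3.5 mL/day/kg, and a ~5–6× half-life collapse
when FcRn binding is switched off — the canonical salvage phenotype. A
minutes-scale endosomal transit (1/k_rec ≈ 15 min) is physiologic. These
values are exposed in `EngineOptions` and documented here because the fit
only adjusts kdeg; uptake/recycling stay at these defaults.

Disease adjustment is a named fold-change applied after the adult fit:
×1.5 on kdeg for inflammatory-disease patients (infliximab), ×2 on target
expression — synthesis and baseline together, preserving the steady state —
for cancer patients (bevacizumab). Drug-specific parameters are otherwise
held fixed for every downstream population; an audit field in the
translation report asserts this.

## Physiology and pediatric scaling

The bundled 70 kg adult reference table carries per-tissue volumes,
vascular/endosomal/interstitial fractions (endosomal space 0.5% of tissue
volume), plasma flows, lymph flow as 0.2% of plasma flow, and a uniform
endosomal FcRn concentration of 49.8 μM. Plasma volume is 3126 mL and the
lymph-node compartment 274 mL at reference weight. Adults scale linearly
in body weight. Pediatric subjects (2–18 years) scale organ and plasma
volumes proportionally to weight and flows allometrically (weight^0.75),
with the brain following an age-indexed maturation fraction since it
approaches adult size early; an age-indexed growth table supplies median
weights used only to reject implausible age/weight combinations (beyond
3-fold of the median). FcRn concentrations are copied from the adult table
unchanged — age-related FcRn expression is deliberately not modeled — and
one frozen physiology represents a subject for an entire simulated trial
(no within-trial growth). There is no neonatal (<2 years) physiology.

## Calibration

Three parameters are fitted per drug — σ_v, σ_L, kdeg — against one or more
observed concentration–time datasets, by minimizing the unweighted
natural-log-scale sum of squares Σ(ln C_sim − ln C_obs)² (concentrations
span >2 decades). The optimizer is bounded Nelder–Mead from the fixed
start (0.95, 0.5, 1e4), with kdeg searched on a log10 scale; bounds are
σ_v ∈ [0.5, 0.999] (the upper bound prevents the non-identifiable σ_v → 1
collapse; the published 0.99 is effectively boundary-like), σ_L ∈
[0.05, 0.999] (the lower range must admit atezolizumab's 0.29), kdeg ∈
[1e2, 1e6] 1/day. Fitting is deterministic; randomness enters only through
the synthetic-data seeds. Simulations inside the fit loop run at relaxed
tolerances (rtol 1e-6, atol 1e-10); a failed simulation returns a large
penalty with a warning instead of aborting the search.

## Sensitivity analysis

The PSA is one-at-a-time on a multiplicative grid that must contain the
reference 1.0, with each PK metric summarized by the normalized index
|d log(metric)/d log(parameter)| from a log–log regression over the grid.
Supported perturbations: FcRn binding kon/koff, endosomal kdeg, uptake and
recycling rates, FcRn concentration globally or in a single named tissue,
and the circulating-target pool. Two choices deserve emphasis:

* **Target-pool semantics.** "Perturbing the circulating target
  concentration" scales the baseline pool at *fixed turnover flux* (ksyn
  held, kdeg_t rescaled to keep the steady state). Scaling the synthesis
  flux together with the pool would make target-mediated elimination —
  which is production-limited while the target is drug-saturated — grow
  linearly with the multiplier and dominate exposure at ×10; that is a
  different question than "is the assumed concentration level important?".
* **Exposure metric.** The PSA reports AUC over the simulated window
  (0–t_end), not extrapolated to infinity: a target perturbation reshapes
  the plunging nonlinear tail on which the terminal-slope extrapolation is
  estimated, so AUC_0–∞ comparisons partly measure extrapolation artifacts.

With these definitions, per-tissue FcRn density indices are each bounded by
that tissue's share of whole-body catabolism (≤0.35 for muscle, <0.1 for
most organs, <0.03 for small ones) and sit well below the binding-kinetics
indices (~0.4–0.8), and a ×0.2–×10 target-pool perturbation moves
bevacizumab exposure at 5 mg/kg by ≈5% — the bulk of which (4.6%) is the
stoichiometric cost of binding and internalizing the enlarged pool.

## Synthetic data

The generator stands in for digitized clinical profiles. Each study design
fixes a population, one virtual representative subject per dose arm
(matching reported central demographics), an IV regimen (weight-based or
absolute, optional cap, bolus or constant-rate infusion, multi-dose), a
sparse sampling schedule (dense early/sparse late for single-dose studies;
peri-dose and trough samples for multi-dose studies), a proportional
log-normal residual CV (default 20%, typical of bioanalytical plus
digitization noise), and a seed. Observations are
`C_obs = C_model·exp(ε)`, ε ~ N(0, √ln(1+CV²)), truncated at 1e-6 μg/mL;
CV = 0 returns exact model values. The bundled panel mirrors the reference
study structure: 9 bevacizumab studies (6 healthy-adult at 1 and 3 mg/kg,
2 adult-patient at 0.1–10 mg/kg, 1 pediatric at 5 and 15 mg/kg for a
13-year-old, 53.65 kg virtual patient), 12 infliximab studies (2 healthy,
8 patient, 2 pediatric including the 13-year-old 42 kg / 210 mg case and a
multi-age multi-dose study), and 2 atezolizumab studies (adult arms at 1,
3, 10, 15, 20 mg/kg; pediatric 15 mg/kg capped at 1200 mg, ages 2–16).

What the generator does *not* emulate — and hence what passing tests do not
show about real data: inter-individual variability (one subject per arm),
assay quantification limits and censoring, model misspecification (the data
are generated by the same model family that is fitted, so self-consistency
tests measure the workflow's internal correctness, not clinical predictive
accuracy), disease-driven changes in tissue composition such as edema, and
within-trial growth.

## Translation workflow

Stages run in order: (1) fit the three drug-specific parameters on the
development dataset(s); (2) simulate the external adult validation studies
(patient studies use the disease-adjusted parameters); (3) apply the
configured disease modifiers; (4) build pediatric physiologies per arm and
predict, holding every drug-specific parameter at its adult-fitted
(disease-adjusted) value. A drug without healthy-adult data develops
directly on adult-patient data and stage 3 is the identity. "Overlay"
acceptability is operationalized as AAFE ≤ 2 and Cmax/AUC fold errors ≤ 2
(the conventional PBPK two-fold criterion; the published judgment is
visual). Observed/simulated comparison interpolates the simulation
log-linearly in concentration at the observed times (exponential decay
between sparse samples); AAFE = 10^(mean |log10(pred/obs)|). A stage
failure marks later stages as skipped rather than aborting.

## Non-compartmental analysis

Linear-up/log-down trapezoidal AUC; terminal slope λz by log-linear
regression over the best subset of ≥3 post-Tmax positive concentrations
chosen by adjusted R² (negative slopes only); AUC_0–∞ = AUC_0–t +
C_last/λz; t½ = ln2/λz; CL = dose/(AUC_0–∞·weight) in mL/day/kg. Fewer
than three positive terminal points flags t½ and AUC_0–∞ as not estimable
while partial metrics are still returned.

## Numerics

* Stiff BDF integration with an analytic Jacobian (the system is a constant
  transport matrix plus bilinear FcRn-binding and TMDD terms whose partials
  are assembled exactly); defaults rtol 1e-8, atol 1e-12 μmol/mL.
* Dose events restart the integrator: boluses add dose/V_plasma to the
  plasma state at the segment boundary, infusions contribute a constant
  μmol/day input over their duration; the output grid always contains the
  dose times, reporting post-dose values there.
* Total drug (body + cumulative-degraded ledgers) is a *linear invariant*
  of the extended ODE system, which linear multistep methods preserve to
  rounding error; the mass-balance residual therefore sits at ~1e-12
  relative and, notably, does not grow when solver tolerances are loosened.
  The ≤1e-6 audit threshold is enforced on every fixture simulation.
* Endogenous IgG tissue baselines are solved per tissue with a 2-unknown
  Newton iteration (vascular/interstitial levels eliminated linearly), then
  the IgG synthesis rate is set to the total degradation flux, making the
  whole baseline stationary to ~1e-9 relative.
* Concentrations may transiently undershoot zero by no more than 1e-9
  μmol/mL (numerical floor, asserted in tests).
* Test problem sizes: single-arm single-dose studies with 9–12 sampling
  points over 84–98 days; fits capped at 200–300 objective evaluations;
  the noisy-recovery study uses 5 seeds. These sizes make every property
  checkable in seconds to a few minutes while leaving the estimates'
  accuracy comfortably inside the asserted tolerances.

## Known limitations

* Star circulation rather than a lung-in-series loop — immaterial for
  antibody kinetics on day timescales, but wrong for first-pass questions.
* Single effective convection term per membrane (no two-pore small/large
  pore partitioning); no tissue-level target expression (plasma TMDD only);
  no subcutaneous absorption, no anti-drug-antibody kinetics.
* The endosomal sub-model is a single-stage compartment with collapsed pH
  handling; the fitted kdeg is a rate constant on endosomal free drug
  (1/day), consistent with its ~1e4/day magnitude given the small
  endosomal volumes, but other software may define an analogous
  "endosomal clearance" differently — fitted values are comparable in
  effect, not necessarily numerically portable.
* Reference physiology values are literature-typical, versioned with the
  package, and documented substitutes rather than reproductions of any
  proprietary default set.
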
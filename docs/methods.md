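# Methods

## Scope and units

The package implements the simulation and estimation machinery of a
mouse-to-monkey translational PK/PD analysis of an IL-10 Fc-fusion
protein. Canonical internal units are hours (time), nM (concentration),
nmol/kg (amounts), and L/kg (volumes); doses are entered in mg/kg and
converted with the construct molecular masses (91,004 Da for the mouse
construct, 90,815 Da for the human construct). All rates and volumes
are per kg, so body weight never appears explicitly. AUCs are reported
in concentration·day at the reporting boundary only.

## Pharmacokinetic models

Mouse (IP dosing): a two-compartment model with a first-order
absorption depot (k_a) and two parallel elimination routes from the
central compartment — first-order non-target clearance (k_el) and a
Michaelis–Menten term V_max·C_p/(K_m + C_p) approximating saturable
target-mediated disposition. Monkey (IV bolus): the same elimination
structure on a three-compartment model. Repeat doses *add* the bolus
(divided by V_c, and by the dose's ADA reduction factor) to the running
state rather than resetting it; with ≥ 14-day intervals and a ~1-day
terminal half-life this is numerically identical to the
initial-condition formulation but stays correct for short intervals.

ADA-driven exposure loss is phenomenological: each dose carries a
reduction factor ≥ 1 dividing the administered amount. The reference
estimates are 3.0/4.9 (2nd/3rd dose at 0.06 mg/kg) and 2530/380 (at
0.18 mg/kg). No mechanistic ADA kinetics are modeled (the titer assay
is qualitative).

Integration uses SciPy's LSODA with rtol 1e−8 and atol 1e−10 nM,
restarted at every dose event; dose times are inserted into the output
grid as exact breakpoints, with the grid point at a bolus reporting the
post-dose value. The default output step is 0.1 h (0.25 h inside
fitting loops, where the PD quantities of interest are
grid-independent at reporting precision for steps ≤ 0.5 h — asserted
in the tests).

AUC(0→∞) is computed by simulating to ≥ 70 days past the last dose and
trapezoid integration, with no analytic tail extrapolation: the
nonlinear model has no closed-form tail, and extending the horizon to
560 days changes the value by < 0.001% because elimination is linear
and fast at sub-K_m concentrations.

## Indirect-response models

IL-18: dC/dt = (baseline(t) + F·E_max·C_p,lag/(EC50 + C_p,lag))·k_out −
k_out·C, C(0) = predose baseline. baseline(t) drifts linearly (signed
slope: +0.15/+0.19 pg/ml/h in mouse control arms, −0.013 pg/ml/h in the
monkey vehicle arm) and is floored at zero with a warning, since the
linear form is otherwise unbounded below. The mouse 72-h lag is applied
to the PD forcing only (C_p,lag(t) = C_p(t − 72 h), zero before the
lag); the PK profile itself is never shifted. The combination
multiplier F (4.4 with anti-PD-1, 1 otherwise) scales E_max; EC50 is
shared between monotherapy and combination, as it reflects the
drug–receptor interaction. The monkey EC50 is taken as 0.082 nM (the
tabulated estimate) everywhere.

Because this ODE is linear with time-varying forcing, it is integrated
with an exponential step that is exact for piecewise-linear forcing
(the per-step recurrence is solved vectorised, in chunks bounded to
avoid overflow of the integrating factor). The same integrator drives
the hematocrit model. Accuracy is limited only by the piecewise-linear
sampling of C_p on the grid.

Hematotoxicity: hematocrit uses inhibition of production,
dC/dt = predose·k_out·(1 − I_max·C_p/(IC50 + C_p)) − k_out·C, with
I_max fixed at 1. Platelets add a precursor pool sharing k_out: drug
inhibits precursor→platelet transfer, the precursor accumulates during
inhibition, and its discharge after washout produces the
above-baseline rebound seen in the data. Both pools start at the
predose level, which the model structure requires for a flat no-drug
baseline. The platelet system (linear, time-varying) is integrated
with LSODA with max step 4 h so bolus-driven forcing transients are
resolved.

Turnover half-lives are 0.693/k_out: 11 h (mouse IL-18), 50 h (monkey
IL-18), 1.8 d (platelets), 16 d (red cells); lifespan-based
equivalents are lifespan × 0.693 (4.5 d and 58 d for 6.5-d platelets
and 85-d red cells).

## Adverse-event grading and MTD

The source figures draw grade lines as percent-of-baseline but never
print the percentages, so the grade scale is an explicit, overridable
configuration input. Defaults derive CTCAE v5 absolute cut-offs
normalised by human lower limits of normal: platelets (LLN 150×10³/µL)
→ G1/G2/G3 boundaries 0.667/0.50/0.333 of baseline; hematocrit via
hemoglobin (LLN 12 g/dL, cut-offs 11/10/8) → 0.917/0.833/0.667. A
value strictly below a boundary takes that grade; a nadir exactly on a
boundary takes the less severe grade. Grades above 3 are not
distinguished (the models carry no mortality/transfusion semantics).

The MTD is the largest dose whose worst simulated grade over three
doses plus ≥ 6 weeks washout is ≤ 2, with no ADA exposure loss
assumed. It is defined on a 0.02 mg/kg dose grid (0.02–0.40), matching
the resolution at which the source dose range was simulated; optional
bisection refinement is available but not the default, because the
published MTDs sit on that grid. Under the default scales the platelet
MTD is 0.06 mg/kg and schedule-independent (fast platelet turnover
resets between doses), while the hematocrit MTD rises with the dosing
interval (0.16/0.22/0.32 mg/kg for Q2W/Q3W/Q4W; slow red-cell turnover
accumulates). The published anemia MTDs (0.14/0.24/0.36) differ by one
grid step per regimen; no single fraction-of-baseline boundary
reproduces all three given these trajectories, so the default CTCAE
derivation is kept rather than calibrating per-regimen boundaries —
anemia MTDs from this package are therefore conditional on the scale
choice, and every MTD report records the scale used.

## Estimation

The objective is a Gaussian −2 log-likelihood with observation
variance σ²/w_i and the scale σ² profiled out at its MLE:
−2LL = n·ln(2π·σ̂²) + Σ ln(1/w_i) + n, σ̂² = (1/n)·Σ w_i(y_i − ŷ_i)².
Weights come from *observed* values: equal, 1/y (mouse PK), or 1/y²
(monkey PK); PD and hematology endpoints use equal weighting. Scaling
data and predictions by c shifts the 1/y² objective by exactly
2n·ln c and leaves estimates unchanged (tested as an identity).
Gaussian priors add Σ((θ−μ)/σ)² (MAP); the reference analysis used a
prior of 0.043 ± 0.022 h⁻¹ on the mouse IL-18 k_out and 50% CV priors
on the monkey EC50 and the dose-reduction factors. AIC = −2LL + 2p and
SBIC = −2LL + p·ln n are exact identities in the results object.

Fitting is sequential: PK first (or fixed at reference estimates),
then each PD/toxicity endpoint conditional on the fixed PK forcing.
The optimizer runs a capped Nelder–Mead simplex from several jittered
starts (fixed seed), each polished with L-BFGS-B; positive parameters
are log-transformed, signed slopes are not. Standard errors come from
cov = 2·H⁻¹ with H the central-difference Hessian of the −2
log-posterior at the optimum; a singular curvature yields NaN SEs
rather than a failure. Below-LLOQ observations are excluded before
fitting.

Published parameter values are treated as inputs for simulation-based
projection; refits are validated by parameter recovery on synthetic
data (noise-free recovery to ~machine precision; < 15% median bias
over 50 seeds at default noise for EC50, E_max, k_out, and baseline),
not by matching published standard errors.

## Synthetic data

The generator reproduces the two study designs: the mouse CT26 PK/PD
study (6 arms × 6 mice — isotype control, anti-PD-1 control, 0.1 and
0.3 mg/kg IP as monotherapy and combination — with 3 PK time points
and ~8 IL-18 time points over 3 weeks, composite sampling) and the
monkey studies (single IV doses 0.005/0.05/0.5 mg/kg with n = 1;
repeat-dose 0.06 and 0.18 mg/kg IV Q2W×3 with n = 3 plus vehicle,
measuring PK, cIL-18, platelets and hematocrit, with the ADA reduction
factors applied to the generating PK). Hematology sampling is dense in
the first days after each dose — the platelet nadir develops within
~3 days — plus weekly washout follow-up.

Residual noise defaults (the source reports no residual-error
magnitudes; these are typical bioanalytical/hematology precision,
chosen once): proportional log-normal, CV 15%, for PK; additive
Gaussian at 10% of the predose baseline for IL-18 and 5% for platelets
and hematocrit. The proportional noise is mean-preserving
(lognormal(−σ²/2, σ)). Composite sampling is modeled as independent
draws per time point with no between-animal random effects, because
the reference analysis modeled average data. Everything is
deterministic given a seed. What passing recovery tests show is that
the estimation machinery inverts the generating model under these
idealised conditions; they cannot certify behaviour under model
misspecification, between-animal variability, or real assay error
structure.

A dilution-correction helper (×17.36) converts diluted mouse
micro-samples to plasma concentrations.

## Dose projection and TI

PD-based: bisection on log-dose (1% relative tolerance) for the
smallest dose whose simulated cIL-18 AUC fold-inductions — against a
constant 13 pg/ml control baseline (the observed median predose level),
no drift, no ADA — meet *all* windowed targets (1.6/1.4/1.3 over
2/3/4 weeks, the levels at which ≥ 80% of mice were tumor-free). The
binding window (2 weeks) depends only on the first dose, so the result
is identical across Q2W/Q3W/Q4W. PK-based: bisection for the dose
whose steady-state per-interval AUC (5th dose) equals the mouse
efficacious AUC(0→∞) (25 nM·day for the combination, 100 nM·day for
monotherapy) divided by the 10-fold in-vitro affinity ratio; the
steady-state interval AUC and single-dose AUC(0→∞) agree to < 0.1%
here and both are computed. Doses are reported at two significant
figures; the TI is the (rounded) MTD over the (rounded) efficacious
dose, and AUC-based exposure multiples use single-dose AUC(0→∞)
ratios, which exceed dose ratios whenever elimination saturates.

## Sensitivity to printed parameter precision

The reference parameter estimates carry two significant figures, and
several projected quantities sit on rounding boundaries at that
precision. With the tabulated values this implementation obtains:
2-week fold-induction at 0.025 mg/kg of 1.59 (prints as 1.6),
PD-based dose 0.026 mg/kg (reported: 0.025), PK-based doses
0.021/0.050 mg/kg (reported: 0.020/0.050), AUC exposure multiple 3.85
(reported: 3.8), and mouse AUC(0→∞) of 22.5/96 nM·day at 0.1/0.3 mg/kg
versus the *observed* (non-compartmental) 25/100 nM·day. The 3–10%
gaps are within what two-significant-figure parameter rounding allows
and are reported as computed, not calibrated away.

## Known limitations

- Average-animal models only; no between-subject variability or
  population (mixed-effects) estimation.
- Michaelis–Menten approximation of target-mediated disposition; no
  explicit binding/internalisation states.
- Phenomenological ADA handling (per-dose reduction factors).
- Tumor dynamics are not modeled; tumor-free percentages are fixed
  observed inputs to the efficacy correlation.
- The grade scale underlying MTDs is an assumption (see above); TI
  values against anemia inherit it.
- Exact −2LL and SE conventions of the original fitting software are
  not documented; agreement is claimed at reporting precision for
  simulated quantities, not at trajectory or SE level.
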
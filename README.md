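# il10pkpd

Translational PK/PD modeling for an IL-10 Fc-fusion protein: the
package bridges mouse antitumor efficacy to cynomolgus-monkey
toxicology to estimate a therapeutic index (TI) in the species whose
toxicity profile is predictive of human safety.

IL-10 Fc-fusion constructs (mFc-mIL-10 in mice, hFc-hIL-10 in monkeys,
~91 kDa) show antitumor activity in syngeneic tumor models, with serum
IL-18 induction as the pharmacodynamic biomarker, and cause anemia and
thrombocytopenia in monkeys but not mice. Because efficacy and toxicity
are observed in different species, the TI is built by (i) quantifying
the exposure–IL-18–efficacy relationship in mice, (ii) establishing
PK/IL-18 and PK/hematotoxicity relationships in monkeys, and (iii)
titrating simulated monkey doses until mouse-derived pharmacodynamic
(or exposure) targets are met.

## Models

**Pharmacokinetics** — compartmental models with parallel linear and
saturable (target-mediated) elimination from the central compartment:

    dC_p/dt = (inputs − transfer)/V_c − k_el·C_p − V_max·C_p / ((K_m + C_p)·V_c)

Mouse: two compartments plus a first-order IP absorption depot.
Monkey: three compartments, IV bolus; antidrug-antibody exposure loss
after repeat doses enters as per-dose reduction factors,
C_p(0⁺) = Dose / (reduction factor · V_c).

**IL-18 induction** — an indirect-response (turnover) model with drug
stimulation of production:

    dC/dt = (baseline(t) + F·E_max·C_p/(EC50 + C_p))·k_out − k_out·C

with a linearly drifting control baseline (rising in mice, declining in
monkeys), a 72-h induction lag in the mouse (delayed T-cell expansion /
IFN-γ / IL-18 cascade), and an anti-PD-1 combination multiplier F on
E_max.

**Hematotoxicity** — inhibition-of-production turnover models:
platelets use a precursor pool sharing k_out with the circulating pool
(reproducing the post-washout rebound above baseline); hematocrit uses
a single pool. Adverse events are graded from the fraction of baseline
at nadir against a configurable grade scale; the maximum tolerated dose
(MTD) is the largest dose keeping all grades ≤ 2 over three doses plus
washout.

**Estimation** — weighted least squares (equal, 1/y, 1/y² weighting)
as a profiled-variance Gaussian −2 log-likelihood, optional Gaussian
(MAP) priors, AIC/SBIC, and asymptotic standard errors from the
numerical curvature. Models follow the statsmodels convention: build a
model object from an observation table, call `fit()`, read a results
object with `params`, `bse`, `aic`, and `summary()`.

**Translation** — PD-based dose projection (bisect the monkey dose
until simulated cIL-18 AUC fold-induction meets the mouse-derived
targets of 1.6/1.4/1.3 over 2/3/4 weeks, against a constant 13 pg/ml
control baseline) and PK-based projection (match the steady-state
per-interval AUC to the mouse efficacious AUC corrected for the 10-fold
receptor-affinity difference); TI = MTD / efficacious dose.

## Worked example

```python
import il10pkpd as m
from il10pkpd import reference as R

pk = R.monkey_pk_reference()          # monkey TMDD PK estimates
il18 = R.monkey_il18_reference()      # cIL-18 turnover estimates

folds = m.fold_induction_at_dose(0.025, pk, il18, interval_days=14.0)
dose = m.project_dose_pd(m.ProjectionSpec("pd_fold"), pk, il18)
mtd = m.find_mtd(pk, R.platelet_reference(), m.DEFAULT_PLATELET_SCALE,
                 interval_days=14.0)
```

This prints:

```
cIL-18 AUC fold-induction at 0.025 mg/kg IV Q2W:
  14 days: 1.59
  21 days: 1.74
  28 days: 1.60
PD-based efficacious dose (Q2W): 0.026 mg/kg
thrombocytopenia MTD (Q2W): 0.06 mg/kg
therapeutic index vs thrombocytopenia: 2.3
```

At 0.025 mg/kg IV every two weeks the monkey IL-18 response is induced
1.6-fold over the first dosing interval — the level associated with
≥ 80% tumor-free mice — and the smallest dose meeting every windowed
target is 0.026 mg/kg. The dose-limiting toxicity is thrombocytopenia
(MTD 0.06 mg/kg regardless of dosing interval), giving a narrow
therapeutic index of about 2.3–2.4.

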
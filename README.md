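# pemfrail

Piecewise exponential hazard models with gamma frailty for recurrent
time-to-event data, built for the question that Cox regression cannot
answer: *does the baseline hazard itself change with time at risk?*

The motivating setting is occupational injury among hourly factory workers,
where time on the job **is** the exposure of interest (experience).  Because
the predictor equals the timescale, the baseline hazard λ₀(t) — not a
covariate effect — is the parameter of interest, and the analysis proceeds
by comparing competing parametric baselines:

* **exponential** — λ₀(t) = λ (the null: experience is inert);
* **Weibull** — λ₀(t) = λ p t^(p−1), p = 1 recovering the exponential;
* **two-piece exponential** — constant rates λ₁, λ₂ that change at a cut
  point τ₁, either fixed *a priori* (e.g. 12 months) or estimated by
  profile likelihood.

Episodes follow the Andersen–Gill counting process on the job clock: each
job contributes at-risk intervals (0, t₁], (t₁, t₂], …, (t_last, c], with
recurrent injuries as events and censoring at job change, termination,
death, or administrative end of study.  Within-worker correlation is
handled by a worker-level gamma frailty u ~ Gamma(1/θ, θ) (mean 1, variance
θ) multiplying the hazard, integrated out analytically.  Missing covariates
(the canonical case: physical demand, measured at only some plants) are
handled by fully-conditional-specification multiple imputation with Rubin's
rules pooling.

The package is aimed at biostatisticians and epidemiologists who need the
full workflow — piecewise fits via the Poisson-GLM equivalence, data-driven
changepoints with an employee-level bootstrap, learning/test model
selection (LRT for nested, BIC/Bayes factors for non-nested pairs), and
MI — plus a synthetic cohort generator so everything is testable without
proprietary data.

## Worked example

```python
import numpy as np
from pemfrail import (SimulationDesign, simulate_cohort,
                      PiecewiseExponentialHazard, profile_changepoint)

# 5,000 workers; true baseline drops from 0.026 to 0.020 injuries per
# person-month after 12 months on the job; male HR 0.71; frailty var 0.5
design = SimulationDesign(n_subjects=5000, seed=1)
cohort, truth = simulate_cohort(design)

est = profile_changepoint(cohort, candidates=np.arange(2.0, 41.0))
print("tau_hat =", est.tau_hat)

fit = PiecewiseExponentialHazard(
    cuts=(12.0,), covariates=tuple(cohort.covariates), frailty=True,
).fit(cohort)
print(fit.hazard_ratio_table().head(3).round(3).to_string(index=False))
print("frailty variance:", round(fit.theta_, 3))
```

Output:

```
tau_hat = 12.0
                    term    hr  ci_low  ci_high   p
piece (0,12] vs (12,inf] 1.222   1.147    1.301 0.0
                    male 0.717   0.655    0.785 0.0
                     age 0.989   0.986    0.993 0.0
frailty variance: 0.566
```

The first row is the "inexperienced period" effect: the injury hazard in
the first 12 months on a job is 1.22 times the later hazard (true value
1.3, inside the CI), conditional on the worker's frailty.  The male hazard
ratio (true 0.71) and the frailty variance (true 0.5) are likewise
recovered within sampling error.

Estimators follow the scikit-learn protocol (`fit`, fitted attributes with
trailing underscores, `get_params`/`set_params`), so they compose with
standard tooling; module-level functions (`profile_changepoint`,
`fcs_impute`, `lrt`, `km_curve`, …) are thin wrappers.

## Command line

```bash
pemfrail simulate --n-subjects 5000 --seed 1 --out sim/
pemfrail fit --model pem --cuts 12 --frailty \
    --covariates male,age,union,smelter,physical_demand \
    --cohort sim/cohort.csv --out fit/
pemfrail changepoint --cohort sim/cohort.csv --bootstrap 400 --out cp/
pemfrail pipeline --config pipeline.yml --cohort sim/cohort.csv --out run/
```

Cohort CSVs use the package's documented counting-process dialect
(`subject_id, job_id, entry_months, exit_months, event, censor_reason,
<covariates…>`; missing cells empty).  Exit codes: 0 success, 2 validation
error, 3 numerical failure.

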
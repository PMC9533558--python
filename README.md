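# dietmetals

Parametric g-formula analysis of joint hypothetical interventions on blood
lead, urinary cadmium and diet quality in NHANES-style mortality cohorts.

Chronic lead and cadmium exposure are associated with all-cause,
cardiovascular and cancer mortality, plausibly through inflammation and
oxidative stress — which suggests that an anti-inflammatory diet could
blunt their effects. This package implements the full epidemiological
pipeline for asking that question with observational cohort data: *what
would the 27-year mortality risk have been had everyone lowered their metal
levels, improved their diet, or both?* It is written for epidemiologists
and biostatisticians who want a tested, reproducible g-computation pipeline
— and, because real survey/mortality linkages are access-restricted, it
ships a synthetic cohort generator with a fully known hazard model so every
estimator property can be verified against exact ground truth.

## The method

Discrete-time hazards are modelled with survey-weighted pooled logistic
regression on person-period data (annual intervals, horizon T = 27):

    logit h_it = β₀ + f(t) + β_Pb·log2(BLL_i) + β_Cd·log2(UCd_i) + β_D·D_i
                 + γ₁·log2(BLL_i)·D_i + γ₂·log2(UCd_i)·D_i + β_Z'·Z_i

where `D` is a diet exposure — the adapted dietary inflammatory index
(DII, positive = anti-inflammatory) or daily fruit/vegetable servings —
and `Z` the baseline adjustment set (age, sex, ethnicity, income-to-poverty
tertile, education, residence, smoking, BMI, physical activity).
Counterfactual risks follow by standardization (the g-formula): exposures
are set by intervention rules such as "cap blood lead at its weighted 5th
percentile" or "floor FV servings at 5/day", hazards are re-predicted, and

    risk_i = 1 − ∏_t (1 − h_it),    risk = Σ_i w_i · risk_i / Σ_i w_i.

Risk ratios and differences are contrasted against the natural course (no
intervention) or the worst-case scenario, with nonparametric bootstrap
percentile 95% CIs (whole-participant resampling, M = 200, percentile
targets and fit recomputed per replicate).

Preprocessing matches survey laboratory conventions: below-detection-limit
lead is imputed as LOD/√2 (1.0 µg/dL → 0.7), urinary cadmium is corrected
for creatinine (µg/g), metals are log2-transformed (one unit = one
doubling), and complete-case exclusion on mortality and covariates is
logged per reason.

## Worked example

```python
from dietmetals import (
    CohortConfig, TrueModel, generate_cohort, prepare_cohort,
    PooledLogisticGFormula, standard_scenarios, run_gformula,
)

model = TrueModel.default()            # harmful metals, protective diet
cohort = generate_cohort(CohortConfig(n_participants=4000, seed=7), model)
prepped, log = prepare_cohort(cohort)

est = PooledLogisticGFormula(cause="all", diet="dii").fit(prepped)
print(f"events: {est.n_events_}, person-years: {est.n_person_years_}")
print(f"log-odds per doubling of blood lead: {est.coef_['lead_log2']:.3f}")

scenarios = standard_scenarios("dii")
results = run_gformula(prepped, scenarios, causes=("all",), M=200, seed=7,
                       references=("natural course",))
print(results[["scenario", "risk", "rr", "rr_lo", "rr_hi", "rd_pts"]]
      .round(3).to_string(index=False))
```

which prints:

```
events: 1317, person-years: 78814
log-odds per doubling of blood lead: 0.205
              scenario  risk    rr  rr_lo  rr_hi  rd_pts
        natural course 0.354 1.000  1.000  1.000   0.000
      lower blood lead 0.285 0.805  0.736  0.870  -6.916
 lower urinary cadmium 0.305 0.860  0.806  0.934  -4.944
     lower both metals 0.236 0.667  0.574  0.770 -11.795
anti-inflammatory diet 0.333 0.942  0.918  0.962  -2.067
             best case 0.229 0.646  0.553  0.764 -12.548
            worst case 0.489 1.382  1.265  1.489  13.519
```

Reading the table: under no intervention the model-standardized 27-year
all-cause mortality risk is 35.4% (it equals the weighted empirical risk —
the natural-course calibration diagnostic). Capping both metals at their
weighted 5th percentiles lowers it to 23.6% (RR 0.67, RD −11.8 percentage
points); adding the diet improvement (best case) reaches RR 0.65, while the
worst case (metals raised to the 95th percentile, diet pushed
pro-inflammatory) raises risk to 48.9%. The fitted 0.205 log-odds per
doubling of blood lead recovers the generator's true value of 0.20.

The same analysis runs from the shell:

```bash
dietmetals simulate --n 4000 --seed 7 --out cohort.csv
dietmetals run --cohort cohort.csv --cause all --m 200 --seed 7 --out-dir results/
```

writing `results.csv`, `results.json` and a rendered `table.md`.

## Scope

The estimator is a point-treatment g-formula: covariates and exposures are
baseline-only, so time-varying confounding is out of scope. Survey
design-based variance (strata/PSU) is not implemented; the bootstrap
resamples individuals. The shipped DII weight table and food-code registry
are synthetic placeholders — editable YAML under `src/dietmetals/data/` —
to be replaced with literature values for substantive analyses. See
`docs/methods.md` for the model, the synthetic data-generating process,
numerical choices and limitations.
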
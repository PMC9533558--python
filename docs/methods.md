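# Methods

## The estimand and the estimator

The package estimates 27-year cumulative mortality risks that a cohort
would have experienced had everyone followed a hypothetical intervention on
blood lead (BLL, µg/dL), creatinine-corrected urinary cadmium (UCd, µg/g)
and/or diet quality, together with risk ratios (RR) and risk differences
(RD) against a reference scenario. The estimator is the parametric
g-formula (g-computation) for a point intervention:

1. Arrange the cohort into person-period form with annual intervals
   `t = 1..27`. A participant with follow-up `f` contributes
   `min(ceil(f), 27)` rows; the event indicator is 1 only in the final row
   and only if the participant died of the cause under analysis inside the
   horizon. Deaths from competing causes are censored at their final
   interval (cause-specific censoring).
2. Fit a pooled logistic regression of the yearly event on a quadratic in
   `t/10`, `log2(BLL)`, `log2(UCd)` (mutually adjusted), one diet exposure
   (the adapted dietary inflammatory index, DII, or daily fruit/vegetable
   servings), `log2(metal) × diet` interaction terms, and the baseline
   adjustment set (age, sex, ethnicity, income-to-poverty tertile,
   education years, residence, smoking, BMI, physical activity). The fit
   maximizes the survey-weighted Bernoulli likelihood (statsmodels GLM);
   coefficient covariance is the HC0 sandwich because survey weights are
   frequency-style, not precision weights.
3. For each scenario, set exposures by the intervention rules, predict
   per-interval hazards `h_t` for every participant with baseline
   covariates fixed (only the time terms vary), cumulate
   `risk_i = 1 − ∏_t (1 − h_it)`, and average with the survey weights.
   Because all covariates are baseline-only this standardization is exact —
   no Monte-Carlo simulation step is involved, and the identity
   intervention reproduces the natural-course risk bit for bit.
4. Confidence intervals are nonparametric bootstrap percentiles (default
   M = 200): whole participants are resampled with replacement, weights
   carried along; percentile targets are re-resolved and the model refitted
   in every replicate; the 2.5th/97.5th percentiles of each risk, RR and RD
   across replicates are reported.

Interventions are ordered rules `(variable, mode, target)` with modes
`cap` (x := min(x, target), "lower to"), `floor` (x := max(x, target),
"increase to") and `set`. Targets are absolute values or percentiles of
the survey-weighted pre-intervention distribution, resolved with a weighted
ECDF using cumulative-weight-midpoint linear interpolation (equal weights
and p = 50 on {1,2,3,4} give 2.5). The shipped scenario set lowers metals
to the 5th percentile and raises them to the 95th in the worst case, with
the diet improved to the 75th DII percentile (or ≥ 5 FV servings/day) and
worsened to the 25th (or ≤ 2 servings); the 25th/75th metal variant is
selectable via scenario parameters or CLI flags.

## Diet scores

The adapted DII is `s · Σ_c w_c z_c` over 24 components, where intakes are
first expressed per 1000 kcal for components flagged for energy adjustment
(density method; a per-component flag allows the residual alternative to be
swapped in), then z-scored against the survey-weighted cohort mean and
population-convention SD. The orientation `s = +1` makes positive scores
anti-inflammatory; `sign_convention="classic"` negates every score. The
shipped component weights are *synthetic placeholders* with plausible signs
and magnitudes — the registry is an editable YAML file intended to be
replaced with literature-derived weights for substantive use. Ethanol grams
is retained as a nutrient component while alcoholic beverages are not food
records; both behaviours are registry-configurable. Fruit/vegetable
servings are `Σ quantity/serving_size` over coded records, with
mixed-dish codes classified by main ingredient and fruit-containing sweets
excluded; the food-code vocabulary is likewise a small synthetic registry.

## The synthetic cohort generator

The generator emulates an NHANES-III-like baseline cohort with a fully
known data-generating process so that every estimator property is testable
against exact ground truth:

- **Covariates.** Age 20–90 (Beta-shaped, mean ≈ 48), sex, ethnicity,
  income tertile, education, residence, smoking and physical-activity
  categories with roughly survey-like margins.
- **Exposures.** Log-normal BLL (marginal GM ≈ 3 µg/dL, ~6–8% below the
  1.0 µg/dL detection limit) and UCd per gram creatinine (GM ≈ 0.36 µg/g),
  both shifted upward with age and smoking and differentially by sex;
  creatinine is drawn separately so the µg/L cadmium column is the product.
  True values are stored alongside the below-LOD flag; the prep stage
  decides what to substitute.
- **Diet.** 24 component intakes log-normal conditional on total energy and
  tilted by a latent diet-quality factor (anti-inflammatory components up,
  pro-inflammatory down), so the computed DII is a noisy function of that
  factor; coded fruit/vegetable records (counts and gram amounts) move with
  the same factor. The stored `dii`/`fv_servings` columns are exactly what
  the scoring module recomputes from the raw columns.
- **Weights.** Log-normal survey weights normalized to mean 1 with
  configurable coefficient of variation (default 0.6).
- **Survival.** Three cause-specific discrete-time logistic hazards (CVD,
  cancer, other) share the exposure/diet/covariate coefficients and differ
  in intercept and time trend. Per year each cause fires independently; the
  smallest uniform draw among fired causes is the recorded cause, and death
  occurs at the end of that interval. Administrative censoring is staggered
  uniformly over 20–27 years (emulating a fixed end of mortality follow-up
  after staggered enrollment; median follow-up ≈ 22 years); deaths are
  observed only within the censoring time.
- **Defaults.** Per-doubling log-odds 0.20 (lead) and 0.15 (cadmium),
  −0.05 per DII unit (or −0.04 per serving when the fruit/vegetable channel
  is active), small protective metal×diet interactions, age 0.085/yr,
  smoking 0.6 (current), and cause intercepts calibrated once so the
  default cohort shows ≈ 37% weighted 27-year all-cause risk with cause
  shares ≈ 31% CVD / 22% cancer / 47% other. Only one diet channel is
  active per model instance, mirroring analyses that model one diet
  exposure at a time; activating both would leave a single-diet hazard
  model misspecified through the diet–diet correlation.

Deliberately **not** emulated: multistage cluster sampling (weights are iid
draws; bootstrap resamples individuals, not design clusters), real
food-code vocabularies, time-varying covariates or exposures, and
measurement panels beyond the variables above. Passing tests therefore
demonstrate estimator correctness under a baseline-only, individually
sampled design, not robustness to NHANES design features.

## Ground-truth oracles

Two independent oracles accompany the generator. The Monte-Carlo oracle
applies an intervention to the *true* exposures, simulates full
trajectories from the true hazards (default 27-year horizon, no
administrative censoring) and reports the weighted cumulative incidence
with a replication-based standard error. The closed-form oracle computes
the same quantity exactly: the yearly all-cause death probability is
`q_t = 1 − ∏_c (1 − h_ct)` and the probability that cause `j` is recorded
is `p_j · Σ_S ∏_{k∈S} p_k ∏_{k∉S}(1 − p_k)/(|S|+1)` over subsets `S` of the
other causes, giving exact cause-specific cumulative incidences that sum to
the all-cause risk.

One estimand subtlety: for a single cause the estimator returns
`1 − ∏(1 − ĥ_ct)` from the cause-specific hazard (a "net" risk, the common
convention for pooled logistic g-formula analyses), whereas the oracle
reports the true cumulative incidence accounting for competing causes. The
two coincide for all-cause mortality, so oracle-equivalence checks are run
on all-cause risk; cause-specific net risks are larger than cumulative
incidences by construction and should be interpreted as such.

## Numerical choices

- Pooled logistic fits use statsmodels GLM (IRLS, tol 1e-10); refits on
  identical data reproduce coefficients to ≤ 1e-8. Rank deficiency is
  detected on the Gram matrix before fitting and reported with the
  implicated terms; non-convergence or |coef| > 50 (separation) is an
  error. Bootstrap replicates use a warm-started Newton solver for the same
  weighted likelihood (agreement with the IRLS fit ~1e-14) and fall back to
  IRLS when a replicate misbehaves; replicates that still fail are dropped
  (an error if more than 10% fail).
- `scenario_risk_se` is a delta-method SE of the standardized risk from the
  HC0 coefficient covariance; it ignores resampling of the standardization
  population and of percentile targets and is used as an uncertainty scale
  in diagnostics, not for inference (the bootstrap is the inferential
  tool).
- Time enters as `t/10` and `(t/10)²` to keep the design well-conditioned;
  the polynomial degree is a parameter and spline-type bases can be added
  through the same design hook.
- The weighted ECDF percentile is continuous in p, equivariant under
  increasing affine maps, and reduces to a standard continuous sample
  quantile under equal weights.
- Below-LOD substitution is LOD/√2 for lead (1.0 µg/dL → 0.7071 ≈ 0.7) and,
  symmetrically and configurably, for cadmium (LOD 0.03 µg/L).
- Degenerate inputs fail loudly: empty percentile input, non-positive
  energy/creatinine/follow-up, zero-variance diet components, hazards
  outside [0,1], zero-reference risk ratios.
- DII standardization is performed once on the analysis cohort; bootstrap
  replicates resample the scored cohort and recompute percentile targets
  and the model fit, but not the z-scoring (by then the score is a fixed
  baseline column). Re-scoring per replicate would perturb the score by
  O(n^-1/2) without changing the resampled contrast distribution
  appreciably.

## Verification design and problem sizes

The acceptance suite checks, at sizes chosen to keep the default test run
short while leaving no property untested: exact preprocessing constants
(LOD/√2; complete-case exclusion arithmetic 16,040 − 1,729 = 14,311; the
24-component registry); identity interventions giving RR = 1, RD = 0
exactly and a null-effect DGP giving intervention RRs within 3 bootstrap
SEs of 1 (n = 5,000, M = 50); agreement of the g-formula with the
Monte-Carlo oracle for all six shipped scenarios within
2·(oracle MC SE + delta-method SE) on an n = 50,000 fully followed cohort;
recovery of the true per-doubling lead coefficient within ±0.03 at the same
size; natural-course calibration within 3 SEs of the weighted empirical
risk; ≥ 88% coverage of the true RR by M = 200 percentile intervals across
25 cohorts of n = 2,000 (per-cohort truth from the closed-form oracle); and
the best-case < natural-course < worst-case ordering. The identification
checks use a generating model with null interactions, an effectively zero
detection limit and full 27-year follow-up so that the estimand is
identified without measurement error; LOD substitution, staggered
censoring and interaction recovery are exercised by the unit suite.

## Known limitations

- Point-treatment g-formula only: covariates and exposures are baseline
  measurements, so time-varying confounding is out of scope by design.
- Variance ignores the survey design (no strata/PSU linearization); the
  individual bootstrap is only design-consistent for independent sampling.
- The shipped DII weights and food codes are synthetic; substantive use
  requires literature weight tables and a real food-coding scheme.
- Cause-specific "risks" are net risks under cause-specific censoring, not
  competing-risk cumulative incidences (see above).
- Percentile-bootstrap intervals may exclude the point estimate in
  pathological resampling situations; bounds are reported as computed.
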
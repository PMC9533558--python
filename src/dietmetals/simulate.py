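"""Synthetic NHANES-III-like cohorts from a fully known hazard model.

The generator draws baseline covariates, right-skewed metal exposures
correlated with age/sex/smoking, a 24-component diet conditional on energy
and a latent diet-quality factor, coded fruit/vegetable records,
heterogeneous survey weights, and survival over annual intervals from
cause-specific discrete-time logistic hazards (cardiovascular, cancer,
other) with metal and diet effects and metal×diet interactions. Because the
data-generating process is known, every downstream estimator can be checked
against exact closed-form counterfactual risks or a brute-force Monte-Carlo
oracle.

Conventions: death occurs at the end of the annual interval in which a
hazard draw fires; when several cause draws fire in the same year the cause
with the smallest uniform draw wins; administrative censoring is staggered
uniformly (emulating a fixed end of mortality follow-up after staggered
enrollment) and never exceeds the 27-year horizon.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from ._rng import substream
from .design import covariate_design, time_design
from .dii import DIIScorer, fv_servings_column
from .interventions import TRUE_COLUMNS, Intervention, apply_intervention, resolve
from .prep import CAUSES
from .registries import DIIWeightRegistry, ServingRegistry

__all__ = [
    "ExposureDist",
    "CauseHazard",
    "TrueModel",
    "CohortConfig",
    "generate_cohort",
    "oracle_counterfactual_risk",
    "closed_form_risk",
    "cause_hazards",
    "OracleResult",
    "write_cohort",
    "read_cohort",
]

# Centers for continuous covariates in the truth linear predictor, so cause
# intercepts describe a reference adult (48-year-old never-smoking woman).
_CENTERS = {"age": 48.0, "education_years": 11.5, "bmi": 26.5}


@dataclass(frozen=True)
class ExposureDist:
    """Log-normal exposure distribution with covariate shifts (ln scale)."""

    ln_gm: float
    sigma: float
    age_slope: float = 0.0  # per year of age, centered at 48
    male: float = 0.0
    smoke_current: float = 0.0
    smoke_former: float = 0.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("exposure sigma must be positive")


@dataclass(frozen=True)
class CauseHazard:
    """Baseline logit hazard for one cause: intercept + time polynomial."""

    intercept: float
    time_lin: float = 0.55  # per decade of follow-up
    time_quad: float = 0.0


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth discrete-time hazard model and exposure distributions.

    Metal effects are logits per doubling (shared across causes); diet
    effects are logits per index unit / per daily serving; interaction
    coefficients multiply log2(metal) x diet products. ``covariate_effects``
    maps canonical design-column names to logit coefficients.
    """

    causes: dict[str, CauseHazard] = field(
        default_factory=lambda: {
            "cvd": CauseHazard(-7.30),
            "cancer": CauseHazard(-7.61),
            "other": CauseHazard(-6.83),
        }
    )
    beta_lead: float = 0.20
    beta_cadmium: float = 0.15
    beta_dii: float = -0.05
    beta_fv: float = 0.0
    beta_lead_dii: float = 0.0
    beta_cadmium_dii: float = 0.0
    beta_lead_fv: float = 0.0
    beta_cadmium_fv: float = 0.0
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.085,
            "sex_male": 0.45,
            "eth_mexican": -0.10,
            "eth_other_hispanic": -0.05,
            "pir_t2": -0.10,
            "pir_t3": -0.20,
            "education_years": -0.02,
            "residence_nonmetro": 0.05,
            "smoke_current": 0.60,
            "smoke_former": 0.25,
            "bmi": 0.01,
            "pa_none": 0.30,
            "pa_1_14": 0.10,
        }
    )
    lead: ExposureDist = field(
        default_factory=lambda: ExposureDist(0.64, 0.65, age_slope=0.009, male=0.55, smoke_current=0.45, smoke_former=0.25)
    )
    cadmium_per_g: ExposureDist = field(
        default_factory=lambda: ExposureDist(-1.15, 0.80, age_slope=0.022, male=-0.30, smoke_current=0.55, smoke_former=0.45)
    )
    creatinine: ExposureDist = field(default_factory=lambda: ExposureDist(0.10, 0.45, male=0.25))
    lod_lead: float = 1.0
    max_followup_years: int = 27

    def __post_init__(self):
        if self.max_followup_years < 1:
            raise ValueError("max_followup_years must be >= 1")
        if self.lod_lead <= 0:
            raise ValueError("lod_lead must be positive")
        for name, val in [
            ("beta_lead", self.beta_lead),
            ("beta_cadmium", self.beta_cadmium),
            ("beta_dii", self.beta_dii),
            ("beta_fv", self.beta_fv),
        ]:
            if not np.isfinite(val):
                raise ValueError(f"{name} must be finite")
        if set(self.causes) != set(CAUSES):
            raise ValueError(f"causes must be exactly {CAUSES}")

    @classmethod
    def default(cls, diet: str = "dii", **overrides) -> "TrueModel":
        """Default harmful-metals / protective-diet model.

        One diet channel is active at a time: ``diet='dii'`` puts the diet
        effect on the inflammatory-index score, ``diet='fv'`` on daily
        fruit/vegetable servings.
        """
        if diet == "dii":
            base = cls(beta_dii=-0.05, beta_fv=0.0, beta_lead_dii=-0.010, beta_cadmium_dii=-0.010)
        elif diet == "fv":
            base = cls(beta_dii=0.0, beta_fv=-0.04, beta_lead_fv=-0.008, beta_cadmium_fv=-0.008)
        else:
            raise ValueError("diet must be 'dii' or 'fv'")
        return replace(base, **overrides) if overrides else base

    @classmethod
    def null(cls) -> "TrueModel":
        """All exposure, diet, interaction and covariate effects zero."""
        return cls(
            beta_lead=0.0,
            beta_cadmium=0.0,
            beta_dii=0.0,
            beta_fv=0.0,
            beta_lead_dii=0.0,
            beta_cadmium_dii=0.0,
            beta_lead_fv=0.0,
            beta_cadmium_fv=0.0,
            covariate_effects={},
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrueModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["causes"] = {k: CauseHazard(**v) for k, v in d["causes"].items()}
        for key in ("lead", "cadmium_per_g", "creatinine"):
            d[key] = ExposureDist(**d[key])
        return cls(**d)


@dataclass(frozen=True)
class CohortConfig:
    """Size, seed and nuisance parameters of a generated cohort.

    ``weight_dispersion`` is the coefficient of variation of the log-normal
    survey weights (normalized to mean 1); ``missingness_rate`` marks an
    exact deterministic fraction of rows with one missing covariate to
    exercise complete-case exclusion; ``admin_censor_range`` staggers the
    administrative censoring time uniformly (years).
    """

    n_participants: int
    seed: int = 0
    weight_dispersion: float = 0.6
    missingness_rate: float = 0.0
    admin_censor_range: tuple[float, float] = (20.0, 27.0)

    def __post_init__(self):
        if not (isinstance(self.n_participants, (int, np.integer)) and self.n_participants > 0):
            raise ValueError("n_participants must be a positive integer")
        if not (0.0 <= float(self.missingness_rate) < 1.0):
            raise ValueError("missingness_rate must be in [0, 1)")
        if not (float(self.weight_dispersion) >= 0.0 and np.isfinite(self.weight_dispersion)):
            raise ValueError("weight_dispersion must be a finite non-negative number")
        lo, hi = self.admin_censor_range
        if not (0 < lo <= hi):
            raise ValueError("admin_censor_range must satisfy 0 < low <= high")


def _exposure_draw(dist: ExposureDist, cov: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    n = len(cov)
    mu = (
        dist.ln_gm
        + dist.age_slope * (cov["age"].to_numpy(float) - _CENTERS["age"])
        + dist.male * (cov["sex"] == "male").to_numpy(float)
        + dist.smoke_current * (cov["smoking"] == "current").to_numpy(float)
        + dist.smoke_former * (cov["smoking"] == "former").to_numpy(float)
    )
    return np.exp(mu + dist.sigma * rng.standard_normal(n))


# Synthetic per-day component geometric means at 2000 kcal (registry order).
_COMPONENT_GM = {
    "carbohydrates": 250.0,
    "proteins": 80.0,
    "alcohol": 5.0,
    "fibers": 16.0,
    "cholesterol": 280.0,
    "saturated_fatty_acids": 27.0,
    "monounsaturated_fatty_acids": 30.0,
    "omega_3": 1.5,
    "omega_6": 14.0,
    "niacin": 22.0,
    "thiamin": 1.6,
    "riboflavin": 1.9,
    "vitamin_b6": 1.8,
    "vitamin_b12": 4.5,
    "iron": 14.0,
    "magnesium": 290.0,
    "zinc": 11.0,
    "vitamin_a": 900.0,
    "vitamin_c": 95.0,
    "vitamin_d": 5.0,
    "vitamin_e": 9.0,
    "folic_acid": 280.0,
    "beta_carotene": 2400.0,
    "caffeine": 150.0,
}


def _generate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = 20.0 + 70.0 * rng.beta(1.2, 1.6, n)
    sex = np.where(rng.random(n) < 0.529, "female", "male")
    eth = rng.choice(["mexican_american", "other_hispanic", "not_hispanic"], n, p=[0.272, 0.026, 0.702])
    pir = rng.integers(1, 4, n)
    edu = np.clip(np.round(rng.normal(11.5, 3.2, n)), 0, 17)
    res = np.where(rng.random(n) < 0.5, "metro", "nonmetro")
    smoke = rng.choice(["never", "current", "former"], n, p=[0.477, 0.313, 0.210])
    bmi = np.exp(rng.normal(np.log(26.5), 0.17, n))
    pa = rng.choice(["none", "1-14", "15+"], n, p=[0.205, 0.356, 0.439])
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "ethnicity": eth,
            "poverty_income_tertile": pir.astype(int),
            "education_years": edu,
            "residence": res,
            "smoking": smoke,
            "bmi": bmi,
            "physical_activity": pa,
        }
    )


def _generate_diet(
    cov: pd.DataFrame, registry: DIIWeightRegistry, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Component intakes conditional on energy and a latent quality factor."""
    n = len(cov)
    q = (
        rng.standard_normal(n)
        - 0.30 * (cov["smoking"] == "current").to_numpy(float)
        + 0.15 * (cov["physical_activity"] == "15+").to_numpy(float)
    )
    energy = np.exp(rng.normal(np.log(2000.0), 0.35, n))
    cols = {"total_energy": energy}
    for comp in registry:
        gm = _COMPONENT_GM[comp.name]
        tilt = 0.25 * np.sign(comp.weight) * q
        mu = np.log(gm) + np.log(energy / 2000.0) + tilt
        cols[comp.name] = np.exp(mu + 0.35 * rng.standard_normal(n))
    return pd.DataFrame(cols, index=cov.index), q


def _generate_fv_records(q: np.ndarray, registry: ServingRegistry, rng: np.random.Generator) -> list[list]:
    fruit_veg = registry.codes("fruit") + registry.codes("vegetable")
    sweets = registry.codes("excluded")
    records: list[list] = []
    lam = np.exp(0.5 + 0.30 * q)
    n_items = rng.poisson(lam)
    for i in range(len(q)):
        items = []
        for _ in range(int(n_items[i])):
            code = fruit_veg[int(rng.integers(len(fruit_veg)))]
            grams = registry[code].serving_size_g * rng.gamma(4.0, 0.3)
            items.append([code, round(float(grams), 1)])
        if sweets and rng.random() < 0.25:
            items.append([sweets[int(rng.integers(len(sweets)))], round(float(rng.uniform(50, 150)), 1)])
        records.append(items)
    return records


def _base_linear_predictors(model: TrueModel, cohort: pd.DataFrame, columns=TRUE_COLUMNS) -> np.ndarray:
    """Time-free part of the per-cause logit hazards, shape (n, n_causes)."""
    Xcov, names = covariate_design(cohort)
    centers = np.array([_CENTERS.get(nm, 0.0) for nm in names])
    beta_cov = np.array([model.covariate_effects.get(nm, 0.0) for nm in names])
    lp = (Xcov - centers) @ beta_cov
    lead = np.log2(cohort[columns["blood_lead"]].to_numpy(float))
    cad = np.log2(cohort[columns["ucd_creat"]].to_numpy(float))
    dii = cohort[columns["dii"]].to_numpy(float) if columns["dii"] in cohort.columns else np.zeros(len(cohort))
    fv = (
        cohort[columns["fv_servings"]].to_numpy(float)
        if columns["fv_servings"] in cohort.columns
        else np.zeros(len(cohort))
    )
    lp = (
        lp
        + model.beta_lead * lead
        + model.beta_cadmium * cad
        + model.beta_dii * dii
        + model.beta_fv * fv
        + model.beta_lead_dii * lead * dii
        + model.beta_cadmium_dii * cad * dii
        + model.beta_lead_fv * lead * fv
        + model.beta_cadmium_fv * cad * fv
    )
    return lp[:, None] + np.array([model.causes[c].intercept for c in CAUSES])[None, :]


def cause_hazards(model: TrueModel, cohort: pd.DataFrame, columns=TRUE_COLUMNS) -> np.ndarray:
    """True per-interval cause-specific hazards, shape (n, horizon, n_causes)."""
    lp = _base_linear_predictors(model, cohort, columns)
    T = model.max_followup_years
    tt, _ = time_design(np.arange(1, T + 1), degree=2)
    tpart = np.array([model.causes[c].time_lin * tt[:, 0] + model.causes[c].time_quad * tt[:, 1] for c in CAUSES]).T
    return expit(lp[:, None, :] + tpart[None, :, :])


def _simulate_survival(h: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Death year (0 = none) and cause index for one trajectory per row."""
    n, T, C = h.shape
    u = rng.random((n, T, C))
    fired = u < h
    any_fire = fired.any(axis=2)
    death_year = np.where(any_fire.any(axis=1), any_fire.argmax(axis=1) + 1, 0)
    died = death_year > 0
    u_masked = np.where(fired, u, np.inf)
    rows = np.nonzero(died)[0]
    cause_idx = np.full(n, -1)
    cause_idx[rows] = u_masked[rows, death_year[rows] - 1, :].argmin(axis=1)
    return death_year, cause_idx


def generate_cohort(
    config: CohortConfig,
    model: TrueModel | None = None,
    dii_registry: DIIWeightRegistry | None = None,
    serving_registry: ServingRegistry | None = None,
) -> pd.DataFrame:
    """Generate a cohort table from the true model; deterministic per seed.

    Stored per participant: baseline covariates, true blood lead (µg/dL)
    with below-LOD flag, urinary cadmium (µg/L) and creatinine (g/L), the
    true creatinine-corrected cadmium, 24 diet component intakes + energy,
    coded fruit/vegetable records, the derived diet scores (``dii``,
    ``fv_servings`` — recomputable from the diet columns), survey weight,
    and follow-up (years), vital status and cause of death simulated from
    the discrete-time hazards.
    """
    model = model or TrueModel.default()
    reg = dii_registry or DIIWeightRegistry.default()
    serv = serving_registry or ServingRegistry.default()
    n = config.n_participants
    seed = config.seed

    cov = _generate_covariates(n, substream(seed, "covariates"))
    cohort = cov.copy()
    cohort.insert(0, "id", np.arange(n))

    cohort["blood_lead"] = _exposure_draw(model.lead, cov, substream(seed, "lead"))
    cohort["lead_below_lod"] = cohort["blood_lead"] < model.lod_lead
    cohort["ucd_creat_true"] = _exposure_draw(model.cadmium_per_g, cov, substream(seed, "cadmium"))
    cohort["urinary_creatinine"] = _exposure_draw(model.creatinine, cov, substream(seed, "creatinine"))
    cohort["urinary_cadmium"] = cohort["ucd_creat_true"] * cohort["urinary_creatinine"]

    diet, q = _generate_diet(cov, reg, substream(seed, "diet"))
    cohort = pd.concat([cohort, diet], axis=1)
    cohort["fv_records"] = _generate_fv_records(q, serv, substream(seed, "fv"))
    cohort["fv_servings"] = fv_servings_column(cohort["fv_records"], serv)

    wrng = substream(seed, "weights")
    cv = float(config.weight_dispersion)
    if cv > 0:
        s2 = np.log1p(cv**2)
        w = np.exp(wrng.normal(-0.5 * s2, np.sqrt(s2), n))
    else:
        w = np.ones(n)
    cohort["survey_weight"] = w

    cohort["dii"] = DIIScorer(registry=reg).score_cohort(cohort, sample_weight=w)

    h = cause_hazards(model, cohort)
    death_year, cause_idx = _simulate_survival(h, substream(seed, "survival"))

    crng = substream(seed, "censoring")
    lo, hi = config.admin_censor_range
    censor = np.minimum(crng.uniform(lo, hi, n), float(model.max_followup_years))
    observed_death = (death_year > 0) & (death_year <= np.floor(censor))
    cohort["died"] = observed_death
    cohort["followup_years"] = np.where(observed_death, death_year.astype(float), censor)
    cause_names = np.array(CAUSES)
    cohort["cause"] = np.where(observed_death, cause_names[np.maximum(cause_idx, 0)], "none")

    n_missing = int(round(float(config.missingness_rate) * n))
    if n_missing:
        mrng = substream(seed, "missingness")
        rows = mrng.choice(n, size=n_missing, replace=False)
        targets = ["bmi", "education_years", "age"]
        for j, r in enumerate(np.sort(rows)):
            cohort.loc[r, targets[j % len(targets)]] = np.nan
    return cohort


# ---------------------------------------------------------------------------
# Counterfactual truth


@dataclass(frozen=True)
class OracleResult:
    risk: float
    se: float
    n_reps: int
    cause: str


def _validate_intervention(intervention: Intervention, cohort: pd.DataFrame) -> None:
    for r in intervention.rules:
        col = TRUE_COLUMNS[r.variable]
        if col not in cohort.columns:
            raise ValueError(f"intervention variable {r.variable!r} not present in cohort ({col!r})")


def _attribution_probs(p: np.ndarray) -> np.ndarray:
    """Exact per-year death probability attributed to each cause.

    Cause j is attributed when its draw fires and is the smallest among all
    fired causes; with independent fires and iid uniforms that is
    ``p_j * sum_S prod_{k in S} p_k prod_{k not in S}(1-p_k) / (|S|+1)``
    over subsets S of the other causes.
    """
    C = p.shape[-1]
    out = np.zeros_like(p)
    for j in range(C):
        others = [k for k in range(C) if k != j]
        acc = np.zeros(p.shape[:-1])
        for size in range(len(others) + 1):
            for S in itertools.combinations(others, size):
                term = np.ones(p.shape[:-1]) / (size + 1)
                for k in others:
                    term = term * (p[..., k] if k in S else (1.0 - p[..., k]))
                acc += term
        out[..., j] = p[..., j] * acc
    return out


def closed_form_risk(
    model: TrueModel,
    cohort: pd.DataFrame,
    intervention: Intervention | None = None,
    cause: str = "all",
    weight_col: str = "survey_weight",
) -> float:
    """Exact weighted counterfactual cumulative incidence under the model.

    All-cause: ``1 - prod_t (1 - q_t)`` with ``q_t`` the all-cause yearly
    death probability; cause-specific: the exact cumulative incidence using
    per-year cause-attribution probabilities.
    """
    df = cohort
    if intervention is not None and not intervention.is_natural_course:
        _validate_intervention(intervention, cohort)
        res = resolve(intervention, cohort, weight_col, columns=TRUE_COLUMNS)
        df = apply_intervention(cohort, res, weight_col, columns=TRUE_COLUMNS)
    h = cause_hazards(model, df)
    q = 1.0 - np.prod(1.0 - h, axis=2)  # all-cause yearly death prob
    surv_before = np.cumprod(1.0 - q, axis=1) / (1.0 - q)  # S_{t-1}
    if cause == "all":
        risk = 1.0 - np.prod(1.0 - q, axis=1)
    else:
        j = CAUSES.index(cause)
        attr = _attribution_probs(h)[:, :, j]
        risk = np.sum(attr * surv_before, axis=1)
    w = df[weight_col].to_numpy(float)
    return float(np.average(risk, weights=w))


def oracle_counterfactual_risk(
    model: TrueModel,
    cohort: pd.DataFrame,
    intervention: Intervention | None = None,
    cause: str = "all",
    n_reps: int = 50,
    seed: int = 0,
    weight_col: str = "survey_weight",
) -> OracleResult:
    """Brute-force Monte-Carlo counterfactual risk from the true hazards.

    Applies the intervention to each participant's true exposures, then
    simulates ``n_reps`` full trajectories per participant over the model
    horizon and returns the survey-weighted mean cumulative incidence of
    the selected cause, with a Monte-Carlo standard error across replicate
    cohorts.
    """
    if cause != "all" and cause not in CAUSES:
        raise ValueError(f"cause must be 'all' or one of {CAUSES}")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    df = cohort
    if intervention is not None and not intervention.is_natural_course:
        _validate_intervention(intervention, cohort)
        res = resolve(intervention, cohort, weight_col, columns=TRUE_COLUMNS)
        df = apply_intervention(cohort, res, weight_col, columns=TRUE_COLUMNS)
    h = cause_hazards(model, df)
    w = df[weight_col].to_numpy(float)
    w = w / w.sum()
    rng = substream(seed, "oracle")
    rep_risks = np.empty(n_reps)
    j = None if cause == "all" else CAUSES.index(cause)
    for r in range(n_reps):
        death_year, cause_idx = _simulate_survival(h, rng)
        died = death_year > 0
        hit = died if j is None else died & (cause_idx == j)
        rep_risks[r] = float(w @ hit)
    return OracleResult(
        risk=float(rep_risks.mean()),
        se=float(rep_risks.std(ddof=1) / np.sqrt(n_reps)),
        n_reps=n_reps,
        cause=cause,
    )


# ---------------------------------------------------------------------------
# CSV round-trip


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV; ``fv_records`` is JSON-encoded in its column."""
    out = cohort.copy()
    if "fv_records" in out.columns:
        out["fv_records"] = [json.dumps(r) for r in out["fv_records"]]
    out.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    if "fv_records" in df.columns:
        df["fv_records"] = [json.loads(r) if isinstance(r, str) else [] for r in df["fv_records"]]
    return df
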
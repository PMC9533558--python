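"""Deterministic cohort preprocessing.

Complete-case exclusions, below-detection-limit imputation (LOD/sqrt(2)),
creatinine correction of urinary cadmium, base-2 log transforms, expansion to
a discrete-time person-period table, weighted percentiles and descriptive
geometric statistics. Everything here is deterministic; all derived
quantities are appended as new named columns, never overwritten in place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dii import DIIScorer, fv_servings_column
from .registries import DIIWeightRegistry, ServingRegistry

__all__ = [
    "PrepConfig",
    "MORTALITY_COLUMNS",
    "ADJUSTMENT_COVARIATES",
    "EXPOSURE_COLUMNS",
    "CAUSES",
    "apply_exclusions",
    "impute_below_lod",
    "creatinine_correct",
    "log2_transform",
    "expand_person_time",
    "weighted_percentile",
    "compute_geometric_stats",
    "prepare_cohort",
]

CAUSES = ("cvd", "cancer", "other")

MORTALITY_COLUMNS = ["followup_years", "died", "cause"]

ADJUSTMENT_COVARIATES = [
    "age",
    "sex",
    "ethnicity",
    "poverty_income_tertile",
    "education_years",
    "residence",
    "smoking",
    "bmi",
    "physical_activity",
]

EXPOSURE_COLUMNS = ["blood_lead", "lead_below_lod", "urinary_cadmium", "urinary_creatinine", "survey_weight"]


@dataclass(frozen=True)
class PrepConfig:
    """Detection limits and discrete-time grid.

    lod_lead in µg/dL, lod_cadmium in µg/L; horizon in whole years with
    annual intervals.
    """

    lod_lead: float = 1.0
    lod_cadmium: float = 0.03
    horizon_years: int = 27
    interval_years: int = 1

    def __post_init__(self):
        if not (self.lod_lead > 0 and self.lod_cadmium > 0):
            raise ValueError("detection limits must be positive")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")
        if self.interval_years != 1:
            raise ValueError("only annual intervals are supported")


def apply_exclusions(raw: pd.DataFrame, required: Sequence[str] | None = None) -> tuple[pd.DataFrame, dict]:
    """Complete-case filter on mortality and adjustment covariates.

    Removes every row with missing data in any required column and returns
    the retained table together with a log: total counts and, per column,
    how many excluded rows were missing that column (a row missing several
    columns is counted under each). Idempotent.
    """
    if required is None:
        required = [c for c in MORTALITY_COLUMNS + ADJUSTMENT_COVARIATES + EXPOSURE_COLUMNS if c in raw.columns]
    missing_any = raw[list(required)].isna().any(axis=1)
    by_reason = {
        col: int(raw.loc[missing_any, col].isna().sum())
        for col in required
        if raw.loc[missing_any, col].isna().any()
    }
    kept = raw.loc[~missing_any].copy()
    log = {
        "n_input": int(len(raw)),
        "n_excluded": int(missing_any.sum()),
        "n_retained": int(len(kept)),
        "by_reason": by_reason,
    }
    if len(kept) == 0:
        import warnings

        warnings.warn("apply_exclusions removed every row", stacklevel=2)
    return kept, log


def impute_below_lod(value, below_lod, lod: float):
    """LOD/sqrt(2) substitution for measurements flagged below detection.

    Values not flagged pass through unchanged (negative unflagged values are
    an error). Scalar or vectorized.
    """
    if lod <= 0:
        raise ValueError("lod must be positive")
    value = np.asarray(value, dtype=float)
    below = np.asarray(below_lod, dtype=bool)
    if np.any(value[~below] < 0):
        raise ValueError("negative concentration without a below-LOD flag")
    out = np.where(below, lod / math.sqrt(2.0), value)
    return float(out) if out.ndim == 0 else out


def creatinine_correct(ucd, creatinine):
    """Urinary cadmium per gram creatinine (µg/L ÷ g/L → µg/g)."""
    ucd = np.asarray(ucd, dtype=float)
    creat = np.asarray(creatinine, dtype=float)
    bad = ~(creat > 0)
    if np.any(bad):
        idx = list(np.nonzero(np.atleast_1d(bad))[0][:20])
        raise ValueError(f"non-positive urinary creatinine at rows {idx}")
    out = ucd / creat
    return float(out) if out.ndim == 0 else out


def log2_transform(x):
    """Base-2 logarithm; one unit = one doubling of the concentration."""
    x = np.asarray(x, dtype=float)
    if np.any(~(x > 0)):
        raise ValueError("log2_transform requires strictly positive values")
    out = np.log2(x)
    return float(out) if out.ndim == 0 else out


def _event_years(cohort: pd.DataFrame, horizon: int) -> tuple[np.ndarray, np.ndarray]:
    fu = cohort["followup_years"].to_numpy(dtype=float)
    if np.any(~(fu > 0)):
        raise ValueError("followup_years must be positive")
    n_years = np.minimum(np.ceil(fu).astype(int), horizon)
    return fu, n_years


def expand_person_time(cohort: pd.DataFrame, config: PrepConfig | None = None, cause: str = "all") -> pd.DataFrame:
    """Person-period table with annual intervals.

    Each participant contributes ``min(ceil(followup_years), horizon)`` rows
    indexed ``t = 1..``; the event indicator is 1 only in the final row and
    only if the participant died of the selected cause within the horizon.
    Deaths from competing causes are censored (all-zero event column), as
    are survivors and administratively censored participants.
    """
    config = config or PrepConfig()
    if cause != "all" and cause not in CAUSES:
        raise ValueError(f"cause must be 'all' or one of {CAUSES}")
    fu, n_years = _event_years(cohort, config.horizon_years)
    died = cohort["died"].to_numpy(dtype=bool)
    cause_col = cohort["cause"].astype(str).to_numpy()
    selected = died & (np.ceil(fu) <= config.horizon_years)
    if cause != "all":
        selected &= cause_col == cause
    idx = np.repeat(np.arange(len(cohort)), n_years)
    t = np.concatenate([np.arange(1, k + 1) for k in n_years]) if len(cohort) else np.array([], int)
    last = np.concatenate([np.arange(k) == k - 1 for k in n_years]) if len(cohort) else np.array([], bool)
    out = cohort.iloc[idx].reset_index(drop=True)
    out["t"] = t
    out["event"] = (last & selected[idx]).astype(int)
    out["at_risk"] = 1
    return out


def weighted_percentile(values, weights, p) -> float:
    """Inverse weighted ECDF with midpoint linear interpolation.

    Plotting positions are the cumulative-weight midpoints
    ``(c_i - w_i/2)/W``; values are linearly interpolated between adjacent
    order statistics and clamped to the min/max outside the midpoint range.
    With equal weights this reduces to a standard continuous sample quantile
    (p=50 on {1,2,3,4} gives 2.5).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("weighted_percentile of an empty set")
    if values.shape != weights.shape:
        raise ValueError("values and weights must align")
    if np.any(~(weights > 0)):
        raise ValueError("weights must be positive")
    p = float(p)
    if not 0.0 <= p <= 100.0:
        raise ValueError("p must be in [0, 100]")
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w)
    pos = (cum - 0.5 * w) / cum[-1]
    return float(np.interp(p / 100.0, pos, v))


def compute_geometric_stats(values, weights=None) -> tuple[float, float]:
    """Weighted geometric mean and geometric standard error.

    GM = exp(weighted mean of ln x); GSE = exp(SE of that weighted mean),
    where the SE uses normalized weights: sqrt(sum w̃_i² (ln x_i − m)²).
    A constant sequence returns (constant, 1.0).
    """
    values = np.asarray(values, dtype=float)
    if np.any(~(values > 0)):
        raise ValueError("geometric statistics need strictly positive values")
    if weights is None:
        w = np.ones_like(values)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(~(w > 0)):
            raise ValueError("weights must be positive")
    w = w / w.sum()
    lx = np.log(values)
    m = w @ lx
    se = math.sqrt(float(w**2 @ (lx - m) ** 2))
    return float(math.exp(m)), float(math.exp(se))


def prepare_cohort(
    raw: pd.DataFrame,
    config: PrepConfig | None = None,
    dii_registry: DIIWeightRegistry | None = None,
    serving_registry: ServingRegistry | None = None,
    rescore_diet: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Full deterministic preprocessing pipeline.

    Applies complete-case exclusions, then appends the analysis columns:
    ``blood_lead_imputed`` (LOD/√2 for flagged rows), ``ucd_creat`` (µg/g),
    ``lead_log2``, ``ucd_creat_log2`` and — when absent or ``rescore_diet``
    — the diet scores ``dii`` and ``fv_servings`` computed from the diet
    component columns and coded food records. Returns (cohort, exclusion log).
    """
    config = config or PrepConfig()
    cohort, log = apply_exclusions(raw)
    cohort = cohort.reset_index(drop=True)
    if len(cohort) == 0:
        return cohort, log
    cohort["blood_lead_imputed"] = impute_below_lod(
        cohort["blood_lead"], cohort["lead_below_lod"], config.lod_lead
    )
    if "cadmium_below_lod" in cohort.columns:
        ucd = impute_below_lod(cohort["urinary_cadmium"], cohort["cadmium_below_lod"], config.lod_cadmium)
    else:
        ucd = cohort["urinary_cadmium"].to_numpy(dtype=float)
    cohort["ucd_creat"] = creatinine_correct(ucd, cohort["urinary_creatinine"])
    cohort["lead_log2"] = log2_transform(cohort["blood_lead_imputed"])
    cohort["ucd_creat_log2"] = log2_transform(cohort["ucd_creat"])

    reg = dii_registry or DIIWeightRegistry.default()
    serv = serving_registry or ServingRegistry.default()
    have_components = all(n in cohort.columns for n in reg.names) and "total_energy" in cohort.columns
    if (rescore_diet or "dii" not in cohort.columns) and have_components:
        cohort["dii"] = DIIScorer(registry=reg).score_cohort(
            cohort, sample_weight=cohort["survey_weight"].to_numpy()
        )
    if (rescore_diet or "fv_servings" not in cohort.columns) and "fv_records" in cohort.columns:
        cohort["fv_servings"] = fv_servings_column(cohort["fv_records"], serv)
    return cohort, log
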
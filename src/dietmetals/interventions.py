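"""Hypothetical intervention rules on exposures and diet quality.

An :class:`Intervention` is an ordered list of rules, each naming a variable
(``blood_lead``, ``ucd_creat``, ``dii`` or ``fv_servings``), a mode and a
target:

* ``cap``   — x := min(x, target)   ("lower to" a threshold; only
  participants above it move)
* ``floor`` — x := max(x, target)   ("increase to"; only those below move)
* ``set``   — x := target           (everyone, sensitivity analyses)

Targets are either absolute values or percentiles of the observed
survey-weighted pre-intervention distribution; :func:`resolve` converts a
percentile-targeted intervention into an absolute-valued one against a given
cohort, so estimator and oracle can share identical thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .prep import log2_transform, weighted_percentile

__all__ = [
    "Rule",
    "Intervention",
    "INTERVENABLE",
    "ANALYSIS_COLUMNS",
    "TRUE_COLUMNS",
    "resolve",
    "apply_intervention",
    "standard_scenarios",
    "load_scenarios",
    "save_scenarios",
]

INTERVENABLE = ("blood_lead", "ucd_creat", "dii", "fv_servings")

# Variable -> cohort column, on the analysis (post-imputation) side and on
# the simulator's ground-truth side.
ANALYSIS_COLUMNS = {
    "blood_lead": "blood_lead_imputed",
    "ucd_creat": "ucd_creat",
    "dii": "dii",
    "fv_servings": "fv_servings",
}
TRUE_COLUMNS = {
    "blood_lead": "blood_lead",
    "ucd_creat": "ucd_creat_true",
    "dii": "dii",
    "fv_servings": "fv_servings",
}

_MODES = ("cap", "floor", "set")


@dataclass(frozen=True)
class Rule:
    """One intervention rule; exactly one of percentile/value is given."""

    variable: str
    mode: str
    percentile: float | None = None
    value: float | None = None

    def __post_init__(self):
        if self.variable not in INTERVENABLE:
            raise ValueError(f"cannot intervene on {self.variable!r}; choose from {INTERVENABLE}")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if (self.percentile is None) == (self.value is None):
            raise ValueError("give exactly one of percentile or value")
        if self.percentile is not None and not 0 <= self.percentile <= 100:
            raise ValueError("percentile must be in [0, 100]")

    @property
    def resolved(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class Intervention:
    """Named, ordered list of rules; an empty list is the natural course."""

    name: str
    rules: tuple[Rule, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "rules", tuple(self.rules))

    @property
    def resolved(self) -> bool:
        return all(r.resolved for r in self.rules)

    @property
    def is_natural_course(self) -> bool:
        return len(self.rules) == 0


def resolve(
    intervention: Intervention,
    cohort: pd.DataFrame,
    weight_col: str = "survey_weight",
    columns: Mapping[str, str] = ANALYSIS_COLUMNS,
) -> Intervention:
    """Replace percentile targets by absolute values from the cohort.

    Percentiles are taken on the survey-weighted pre-intervention
    distribution of each variable's natural-scale column.
    """
    w = cohort[weight_col].to_numpy(dtype=float)
    rules = []
    for r in intervention.rules:
        if r.resolved:
            rules.append(r)
            continue
        col = columns[r.variable]
        if col not in cohort.columns:
            raise ValueError(f"cannot resolve {r.variable!r}: column {col!r} absent from cohort")
        target = weighted_percentile(cohort[col].to_numpy(dtype=float), w, r.percentile)
        rules.append(replace(r, percentile=None, value=float(target)))
    return Intervention(intervention.name, tuple(rules))


def _apply_rule(x: np.ndarray, mode: str, target: float) -> np.ndarray:
    if mode == "cap":
        return np.minimum(x, target)
    if mode == "floor":
        return np.maximum(x, target)
    return np.full_like(x, target)


def apply_intervention(
    cohort: pd.DataFrame,
    intervention: Intervention,
    weight_col: str = "survey_weight",
    columns: Mapping[str, str] = ANALYSIS_COLUMNS,
) -> pd.DataFrame:
    """Return a modified copy of the cohort under the intervention.

    Percentile targets are resolved on the pre-intervention weighted
    distribution; rules apply in order; untouched variables are unchanged
    and the input frame is never mutated. The derived ``lead_log2`` /
    ``ucd_creat_log2`` columns are recomputed when their metal changes.
    """
    res = resolve(intervention, cohort, weight_col, columns)
    out = cohort.copy()
    for r in res.rules:
        col = columns[r.variable]
        if col not in out.columns:
            raise ValueError(f"intervention variable {r.variable!r}: column {col!r} absent")
        out[col] = _apply_rule(out[col].to_numpy(dtype=float), r.mode, r.value)
        if r.variable == "blood_lead" and "lead_log2" in out.columns and col == "blood_lead_imputed":
            out["lead_log2"] = log2_transform(out[col])
        if r.variable == "ucd_creat" and "ucd_creat_log2" in out.columns and col == "ucd_creat":
            out["ucd_creat_log2"] = log2_transform(out[col])
    return out


def standard_scenarios(
    diet: str = "dii",
    metal_low_pct: float = 5.0,
    metal_high_pct: float = 95.0,
    dii_high_pct: float = 75.0,
    dii_low_pct: float = 25.0,
    fv_target: float = 5.0,
    fv_worst: float = 2.0,
) -> list[Intervention]:
    """The study's scenario set for one diet exposure (``dii`` or ``fv``).

    Natural course; lower each metal to the low percentile; lower both;
    improve diet (raise the inflammatory-index score to its 75th percentile,
    or raise fruit/vegetable servings to 5/day); best case (both metals down
    + better diet); worst case (both metals up to the high percentile + diet
    worsened). Percentile defaults follow the headline tables (5th/95th).
    """
    if diet not in ("dii", "fv"):
        raise ValueError("diet must be 'dii' or 'fv'")
    lead_dn = Rule("blood_lead", "cap", percentile=metal_low_pct)
    cad_dn = Rule("ucd_creat", "cap", percentile=metal_low_pct)
    lead_up = Rule("blood_lead", "floor", percentile=metal_high_pct)
    cad_up = Rule("ucd_creat", "floor", percentile=metal_high_pct)
    if diet == "dii":
        diet_good = Rule("dii", "floor", percentile=dii_high_pct)
        diet_bad = Rule("dii", "cap", percentile=dii_low_pct)
        diet_label = "anti-inflammatory diet"
    else:
        diet_good = Rule("fv_servings", "floor", value=fv_target)
        diet_bad = Rule("fv_servings", "cap", value=fv_worst)
        diet_label = "higher FV servings"
    return [
        Intervention("natural course"),
        Intervention("lower blood lead", (lead_dn,)),
        Intervention("lower urinary cadmium", (cad_dn,)),
        Intervention("lower both metals", (lead_dn, cad_dn)),
        Intervention(diet_label, (diet_good,)),
        Intervention("best case", (lead_dn, cad_dn, diet_good)),
        Intervention("worst case", (lead_up, cad_up, diet_bad)),
    ]


def load_scenarios(path: str | Path) -> list[Intervention]:
    """Scenario list from a YAML file of {name, rules: [...]} entries."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    out = []
    for item in payload["scenarios"]:
        rules = tuple(
            Rule(
                variable=r["variable"],
                mode=r["mode"],
                percentile=r.get("percentile"),
                value=r.get("value"),
            )
            for r in item.get("rules", [])
        )
        out.append(Intervention(item["name"], rules))
    return out


def save_scenarios(scenarios: Iterable[Intervention], path: str | Path) -> None:
    payload = {
        "scenarios": [
            {
                "name": s.name,
                "rules": [
                    {
                        "variable": r.variable,
                        "mode": r.mode,
                        **({"percentile": r.percentile} if r.percentile is not None else {}),
                        **({"value": r.value} if r.value is not None else {}),
                    }
                    for r in s.rules
                ],
            }
            for s in scenarios
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
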
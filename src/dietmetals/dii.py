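"""Adapted dietary inflammatory index and fruit/vegetable serving scores.

The adapted index is a weighted sum of standardized, energy-adjusted daily
component intakes from a 24-hour recall:

    DII_i = s * sum_c  w_c * z_ic,       z_ic = (x_ic - mu_c) / sd_c

where ``x_ic`` is the (optionally per-1000 kcal) intake of component ``c``,
``mu_c``/``sd_c`` are survey-weighted cohort mean and SD (population, i.e.
denominator-n, convention), ``w_c`` the component's inflammatory weight, and
``s = +1`` under the convention used here (positive score ⇒ anti-inflammatory
diet) or ``s = -1`` under the classic orientation.

Daily fruit-and-vegetable servings are the sum over coded food records of
``quantity / serving_size`` for fruit and vegetable codes; excluded codes
(sweets where fruit is not the main ingredient) contribute zero.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .registries import DIIWeightRegistry, ServingRegistry

__all__ = [
    "energy_adjust",
    "standardize",
    "compute_dii",
    "compute_fv_servings",
    "fv_servings_column",
    "DIIScorer",
]

ENERGY_COL = "total_energy"


def _component_frame(diet: pd.DataFrame, registry: DIIWeightRegistry) -> pd.DataFrame:
    missing = [n for n in registry.names if n not in diet.columns]
    if missing:
        raise ValueError(f"diet matrix is missing components: {missing}")
    return diet[registry.names]


def energy_adjust(diet: pd.DataFrame, registry: DIIWeightRegistry) -> pd.DataFrame:
    """Express flagged component intakes per 1000 kcal (density method).

    ``diet`` must carry one column per registry component plus
    ``total_energy`` (kcal/day). Components with ``energy_adjust=False`` pass
    through unchanged. Rows with non-positive energy are rejected.
    """
    if ENERGY_COL not in diet.columns:
        raise ValueError(f"diet matrix needs a {ENERGY_COL!r} column (kcal/day)")
    energy = diet[ENERGY_COL].to_numpy(dtype=float)
    bad = ~(energy > 0) | ~np.isfinite(energy)
    if bad.any():
        ids = list(diet.index[bad][:20])
        raise ValueError(f"non-positive total energy for participants {ids}")
    comp = _component_frame(diet, registry).astype(float)
    out = comp.copy()
    mask = registry.energy_adjust_mask
    cols = [n for n, m in zip(registry.names, mask) if m]
    out[cols] = comp[cols].to_numpy() / energy[:, None] * 1000.0
    return out


def standardize(adjusted: pd.DataFrame, weights: Sequence[float] | None = None) -> pd.DataFrame:
    """Survey-weighted z-scores per component (population-SD convention).

    The weighted mean of each returned column is 0 and the weighted SD is 1;
    rescaling all weights by a common factor leaves the result unchanged.
    A zero-variance component is an error (its z-score is undefined).
    """
    if len(adjusted) < 2:
        raise ValueError("standardize needs at least two participants")
    x = adjusted.to_numpy(dtype=float)
    if weights is None:
        w = np.ones(len(adjusted))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(adjusted),):
            raise ValueError("weights must be one per participant")
        if not np.all(w > 0):
            raise ValueError("weights must be positive")
    w = w / w.sum()
    mu = w @ x
    var = w @ (x - mu) ** 2
    zero = var <= 0
    if zero.any():
        names = [c for c, z in zip(adjusted.columns, zero) if z]
        raise ValueError(f"zero-variance components cannot be standardized: {names}")
    z = (x - mu) / np.sqrt(var)
    return pd.DataFrame(z, index=adjusted.index, columns=adjusted.columns)


def compute_dii(
    z: pd.DataFrame,
    registry: DIIWeightRegistry,
    sign_convention: str = "adapted",
) -> pd.Series:
    """Weighted sum of component z-scores.

    ``sign_convention="adapted"`` keeps the registry orientation (positive =
    anti-inflammatory); ``"classic"`` negates every score so positive values
    mark a pro-inflammatory diet, as in the original index literature.
    """
    if sign_convention not in ("adapted", "classic"):
        raise ValueError("sign_convention must be 'adapted' or 'classic'")
    if list(z.columns) != registry.names:
        extra = set(z.columns) - set(registry.names)
        missing = set(registry.names) - set(z.columns)
        if extra or missing:
            raise ValueError(
                f"z-score columns do not match registry components "
                f"(missing={sorted(missing)}, unexpected={sorted(extra)})"
            )
        z = z[registry.names]
    s = 1.0 if sign_convention == "adapted" else -1.0
    score = s * (z.to_numpy(dtype=float) @ registry.weights)
    return pd.Series(score, index=z.index, name="dii")


def _parse_records(records) -> list[tuple[str, float]]:
    if isinstance(records, str):
        records = json.loads(records) if records.strip() else []
    return [(str(code), float(qty)) for code, qty in records]


def compute_fv_servings(records, registry: ServingRegistry) -> float:
    """Daily fruit-and-vegetable servings from coded food records.

    ``records`` is an iterable of ``(food_code, grams)`` pairs (or its JSON
    serialization). Unknown codes are an error; excluded codes add nothing.
    """
    pairs = _parse_records(records)
    unknown = sorted({code for code, _ in pairs if code not in registry})
    if unknown:
        raise ValueError(f"unknown food codes: {unknown}")
    total = 0.0
    for code, qty in pairs:
        entry = registry[code]
        if entry.group == "excluded":
            continue
        total += qty / entry.serving_size_g
    return total


def fv_servings_column(records: Iterable, registry: ServingRegistry) -> np.ndarray:
    """Vectorized :func:`compute_fv_servings` over a column of record lists."""
    return np.array([compute_fv_servings(r, registry) for r in records], dtype=float)


class DIIScorer(TransformerMixin, BaseEstimator):
    """Transformer computing the adapted dietary inflammatory index.

    ``fit`` learns the survey-weighted component means and SDs of the
    energy-adjusted intakes; ``transform`` returns the per-participant score
    as an ``(n, 1)`` array, so the scorer composes with sklearn pipelines.
    For the usual in-cohort scoring (standardization against the analysed
    cohort itself) use :meth:`score_cohort`.

    Parameters
    ----------
    registry : DIIWeightRegistry, optional
        Component registry; the packaged 24-component default if omitted.
    sign_convention : {"adapted", "classic"}
        "adapted": positive score = anti-inflammatory diet (default).
    """

    def __init__(self, registry: DIIWeightRegistry | None = None, sign_convention: str = "adapted"):
        self.registry = registry
        self.sign_convention = sign_convention

    def _registry(self) -> DIIWeightRegistry:
        return self.registry if self.registry is not None else DIIWeightRegistry.default()

    def fit(self, X: pd.DataFrame, y=None, sample_weight=None):
        reg = self._registry()
        adjusted = energy_adjust(X, reg)
        if len(adjusted) < 2:
            raise ValueError("DIIScorer needs at least two participants to fit")
        w = np.ones(len(adjusted)) if sample_weight is None else np.asarray(sample_weight, float)
        if not np.all(w > 0):
            raise ValueError("sample_weight must be positive")
        w = w / w.sum()
        x = adjusted.to_numpy(dtype=float)
        mu = w @ x
        var = w @ (x - mu) ** 2
        zero = var <= 0
        if zero.any():
            names = [c for c, z in zip(adjusted.columns, zero) if z]
            raise ValueError(f"zero-variance components cannot be standardized: {names}")
        self.components_ = reg.names
        self.mean_ = mu
        self.scale_ = np.sqrt(var)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "mean_"):
            raise ValueError("DIIScorer is not fitted")
        reg = self._registry()
        adjusted = energy_adjust(X, reg)
        z = (adjusted.to_numpy(dtype=float) - self.mean_) / self.scale_
        s = 1.0 if self.sign_convention == "adapted" else -1.0
        return (s * (z @ reg.weights))[:, None]

    def score_cohort(self, X: pd.DataFrame, sample_weight=None) -> pd.Series:
        """Fit on the cohort and return its scores as a named Series."""
        self.fit(X, sample_weight=sample_weight)
        return pd.Series(self.transform(X)[:, 0], index=X.index, name="dii")

    def get_feature_names_out(self, input_features=None):
        return np.array(["dii"])
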
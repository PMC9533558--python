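"""Canonical design encodings for the baseline adjustment set and time terms.

One fixed dummy coding of the adjustment covariates (age, sex, ethnicity,
income-to-poverty tertile, education, residence, smoking, BMI, physical
activity) is shared between the synthetic data-generating process and the
pooled logistic hazard model, so "well-specified" has a single concrete
meaning throughout the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["COVARIATE_DESIGN_COLUMNS", "covariate_design", "time_design"]

# Reference levels: female; not_hispanic; tertile 1; metro; never smoker;
# physical activity '15+'.
COVARIATE_DESIGN_COLUMNS = [
    "age",
    "sex_male",
    "eth_mexican",
    "eth_other_hispanic",
    "pir_t2",
    "pir_t3",
    "education_years",
    "residence_nonmetro",
    "smoke_current",
    "smoke_former",
    "bmi",
    "pa_none",
    "pa_1_14",
]


def covariate_design(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Numeric design block for the baseline adjustment covariates."""
    n = len(df)
    X = np.empty((n, len(COVARIATE_DESIGN_COLUMNS)), dtype=float)
    sex = df["sex"].astype(str)
    eth = df["ethnicity"].astype(str)
    pir = df["poverty_income_tertile"].to_numpy()
    res = df["residence"].astype(str)
    smoke = df["smoking"].astype(str)
    pa = df["physical_activity"].astype(str)
    X[:, 0] = df["age"].to_numpy(dtype=float)
    X[:, 1] = (sex == "male").to_numpy(dtype=float)
    X[:, 2] = (eth == "mexican_american").to_numpy(dtype=float)
    X[:, 3] = (eth == "other_hispanic").to_numpy(dtype=float)
    X[:, 4] = (pir == 2).astype(float)
    X[:, 5] = (pir == 3).astype(float)
    X[:, 6] = df["education_years"].to_numpy(dtype=float)
    X[:, 7] = (res == "nonmetro").to_numpy(dtype=float)
    X[:, 8] = (smoke == "current").to_numpy(dtype=float)
    X[:, 9] = (smoke == "former").to_numpy(dtype=float)
    X[:, 10] = df["bmi"].to_numpy(dtype=float)
    X[:, 11] = (pa == "none").to_numpy(dtype=float)
    X[:, 12] = (pa == "1-14").to_numpy(dtype=float)
    return X, list(COVARIATE_DESIGN_COLUMNS)


def time_design(t: np.ndarray, degree: int = 2) -> tuple[np.ndarray, list[str]]:
    """Polynomial terms in the interval index, scaled by decade (t/10)."""
    if degree < 1:
        raise ValueError("time polynomial degree must be >= 1")
    t = np.asarray(t, dtype=float) / 10.0
    cols = [t**k for k in range(1, degree + 1)]
    names = ["t10" if k == 1 else f"t10_pow{k}" for k in range(1, degree + 1)]
    return np.column_stack(cols), names
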
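"""Parametric g-formula with survey-weighted pooled logistic hazards.

The estimator fits a discrete-time hazard model on person-period data —
a logistic regression of the yearly death indicator on follow-up time
(quadratic by default), log2 blood lead, log2 creatinine-corrected urinary
cadmium (mutually adjusted), one diet exposure (inflammatory-index score or
daily fruit/vegetable servings), metal×diet interactions and the baseline
adjustment set — weighted by the survey weights. Counterfactual 27-year
risks are then computed by standardization: for every participant the
fitted per-interval hazards are evaluated with exposures set by an
intervention (covariates fixed at baseline, only time varies), cumulated to
``1 - prod_t(1 - h_t)``, and averaged with the survey weights. Because all
covariates are baseline-only this standardization is exact (closed form);
no Monte-Carlo simulation step is needed.

Contrasts are risk ratios and risk differences against a reference scenario
(natural course or worst case), with nonparametric bootstrap percentile
confidence intervals: participants are resampled with replacement (weights
carried along), percentile targets recomputed, the model refitted and every
scenario risk and contrast re-estimated per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator

from ._rng import substream
from .design import covariate_design, time_design
from .interventions import ANALYSIS_COLUMNS, Intervention, apply_intervention, resolve
from .prep import CAUSES, PrepConfig, expand_person_time, weighted_percentile

__all__ = [
    "PooledLogisticGFormula",
    "GFormulaError",
    "fit_pooled_logistic",
    "estimate_scenario_risk",
    "cumulative_risk",
    "contrast",
    "bootstrap_ci",
    "run_gformula",
]

_DIET_COLUMN = {"dii": "dii", "fv": "fv_servings"}


class GFormulaError(RuntimeError):
    """Fit or bootstrap failure with diagnostics."""


def cumulative_risk(hazards) -> float | np.ndarray:
    """Discrete-time cumulative risk ``1 - prod_t (1 - h_t)``.

    Accepts a 1-d hazard sequence or an ``(n, T)`` array (risk per row).
    """
    h = np.asarray(hazards, dtype=float)
    if np.any((h < 0) | (h > 1) | ~np.isfinite(h)):
        raise ValueError("hazards must lie in [0, 1]")
    out = 1.0 - np.prod(1.0 - h, axis=-1)
    return float(out) if out.ndim == 0 else out


def contrast(risk_intervened: float, risk_reference: float) -> tuple[float, float]:
    """Risk ratio and risk difference (percentage points) vs a reference."""
    rd = (risk_intervened - risk_reference) * 100.0
    if risk_reference <= 0:
        raise ZeroDivisionError(f"risk ratio undefined for zero reference (RD = {rd:+.4f} points)")
    return risk_intervened / risk_reference, rd


@dataclass
class _Compiled:
    """Numpy snapshot of a prepped cohort for the fast fit/predict path."""

    Xcov: np.ndarray  # (n, p_cov)
    lead_log2: np.ndarray
    ucd_log2: np.ndarray
    diet: np.ndarray
    lead_nat: np.ndarray  # natural-scale values for percentile resolution
    ucd_nat: np.ndarray
    w: np.ndarray
    n_years: np.ndarray  # person-period rows contributed
    event_sel: np.ndarray  # died of the selected cause within the horizon

    def take(self, idx: np.ndarray) -> "_Compiled":
        return _Compiled(
            self.Xcov[idx],
            self.lead_log2[idx],
            self.ucd_log2[idx],
            self.diet[idx],
            self.lead_nat[idx],
            self.ucd_nat[idx],
            self.w[idx],
            self.n_years[idx],
            self.event_sel[idx],
        )

    @property
    def n(self) -> int:
        return len(self.w)


class PooledLogisticGFormula(BaseEstimator):
    """Survey-weighted pooled logistic g-formula estimator.

    Parameters
    ----------
    cause : {"all", "cvd", "cancer", "other"}
        Outcome; competing causes are censored at their final interval.
    diet : {"dii", "fv"}
        Diet exposure entering the hazard model (``dii`` column or
        ``fv_servings`` column of the prepped cohort).
    time_degree : int
        Degree of the polynomial in the interval index (default quadratic).
    include_interactions : bool
        Include log2(metal) × diet product terms (default True).
    horizon : int
        Risk horizon in years.
    weight_col : str
        Survey-weight column.

    Attributes (after ``fit``)
    --------------------------
    coef_ : pd.Series of named logit-scale coefficients
    cov_params_ : np.ndarray coefficient covariance
    converged_ : bool, n_events_ : int, n_person_years_ : int
    """

    def __init__(
        self,
        cause: str = "all",
        diet: str = "dii",
        time_degree: int = 2,
        include_interactions: bool = True,
        horizon: int = 27,
        weight_col: str = "survey_weight",
    ):
        self.cause = cause
        self.diet = diet
        self.time_degree = time_degree
        self.include_interactions = include_interactions
        self.horizon = horizon
        self.weight_col = weight_col

    # -- compilation -------------------------------------------------------

    def _check_params(self):
        if self.cause != "all" and self.cause not in CAUSES:
            raise ValueError(f"cause must be 'all' or one of {CAUSES}")
        if self.diet not in _DIET_COLUMN:
            raise ValueError("diet must be 'dii' or 'fv'")

    def _compile(self, cohort: pd.DataFrame) -> _Compiled:
        self._check_params()
        diet_col = _DIET_COLUMN[self.diet]
        for col in ("lead_log2", "ucd_creat_log2", diet_col, self.weight_col, "followup_years", "died", "cause"):
            if col not in cohort.columns:
                raise ValueError(f"prepped cohort is missing column {col!r}")
        Xcov, _ = covariate_design(cohort)
        fu = cohort["followup_years"].to_numpy(float)
        if np.any(~(fu > 0)):
            raise ValueError("followup_years must be positive")
        n_years = np.minimum(np.ceil(fu).astype(int), self.horizon)
        died = cohort["died"].to_numpy(bool)
        sel = died & (np.ceil(fu) <= self.horizon)
        if self.cause != "all":
            sel &= cohort["cause"].astype(str).to_numpy() == self.cause
        return _Compiled(
            Xcov=Xcov,
            lead_log2=cohort["lead_log2"].to_numpy(float),
            ucd_log2=cohort["ucd_creat_log2"].to_numpy(float),
            diet=cohort[diet_col].to_numpy(float),
            lead_nat=cohort[ANALYSIS_COLUMNS["blood_lead"]].to_numpy(float)
            if ANALYSIS_COLUMNS["blood_lead"] in cohort.columns
            else np.exp2(cohort["lead_log2"].to_numpy(float)),
            ucd_nat=cohort[ANALYSIS_COLUMNS["ucd_creat"]].to_numpy(float)
            if ANALYSIS_COLUMNS["ucd_creat"] in cohort.columns
            else np.exp2(cohort["ucd_creat_log2"].to_numpy(float)),
            w=cohort[self.weight_col].to_numpy(float),
            n_years=n_years,
            event_sel=sel,
        )

    def _term_names(self) -> list[str]:
        _, tnames = time_design(np.array([1.0]), self.time_degree)
        diet_name = _DIET_COLUMN[self.diet]
        names = ["const", *tnames, "lead_log2", "ucd_creat_log2", diet_name]
        if self.include_interactions:
            names += [f"lead_log2:{diet_name}", f"ucd_creat_log2:{diet_name}"]
        from .design import COVARIATE_DESIGN_COLUMNS

        return names + list(COVARIATE_DESIGN_COLUMNS)

    def _person_time_design(self, c: _Compiled) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ridx = np.repeat(np.arange(c.n), c.n_years)
        t = np.concatenate([np.arange(1, k + 1) for k in c.n_years])
        tt, _ = time_design(t, self.time_degree)
        blocks = [np.ones((len(t), 1)), tt]
        expo = [c.lead_log2[ridx], c.ucd_log2[ridx], c.diet[ridx]]
        if self.include_interactions:
            expo += [c.lead_log2[ridx] * c.diet[ridx], c.ucd_log2[ridx] * c.diet[ridx]]
        blocks.append(np.column_stack(expo))
        blocks.append(c.Xcov[ridx])
        X = np.hstack(blocks)
        y = np.zeros(len(t))
        last = np.cumsum(c.n_years) - 1
        y[last[c.event_sel]] = 1.0
        return X, y, c.w[ridx]

    # -- fitting -----------------------------------------------------------

    @staticmethod
    def _newton_logistic(X, y, w, start, tol=1e-10, maxiter=50):
        """Warm-started Newton solver for the weighted Bernoulli MLE.

        Maximizes the same weighted log-likelihood as the statsmodels fit;
        used in the bootstrap hot path where the full-cohort coefficients
        provide a starting point a few steps from the optimum.
        """
        beta = np.array(start, dtype=float)
        for _ in range(maxiter):
            mu = expit(X @ beta)
            grad = X.T @ (w * (y - mu))
            W = w * mu * (1.0 - mu)
            H = (X * W[:, None]).T @ X
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError as exc:
                raise GFormulaError(f"singular Hessian in Newton refit: {exc}") from exc
            beta += step
            if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 50:
                raise GFormulaError("Newton refit diverged (possible separation)")
            if np.max(np.abs(step)) < tol:
                return beta
        raise GFormulaError("Newton refit did not converge")

    def _fit_arrays(self, X: np.ndarray, y: np.ndarray, w: np.ndarray, start=None, compute_cov=True) -> tuple[np.ndarray, np.ndarray | None]:
        if y.sum() < 1:
            raise GFormulaError("no events for the selected cause; cannot fit the hazard model")
        if start is not None and not compute_cov:
            try:
                return self._newton_logistic(X, y, w, start), None
            except GFormulaError:
                pass  # fall through to the IRLS fit below
        # rank check on the (cheap) Gram matrix
        gram = X.T @ X
        eigvals, eigvecs = np.linalg.eigh(gram)
        if eigvals[0] < 1e-10 * eigvals[-1]:
            null = np.abs(eigvecs[:, 0])
            names = [n for n, v in zip(self._term_names(), null) if v > 0.3]
            raise GFormulaError(f"design matrix is rank deficient; collinear terms likely among {names}")
        model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                # robust (sandwich) covariance: survey weights are not
                # precision weights, so the model-based covariance would
                # understate coefficient uncertainty
                res = model.fit(start_params=start, maxiter=100, tol=1e-10, cov_type="HC0")
        except Exception as exc:  # pragma: no cover - statsmodels internal failures
            raise GFormulaError(f"pooled logistic fit failed: {exc}") from exc
        beta = np.asarray(res.params)
        if not res.converged or not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 50:
            raise GFormulaError(
                "pooled logistic fit did not converge (possible separation); "
                f"max|coef| = {np.max(np.abs(beta)):.3g}"
            )
        return beta, np.asarray(res.cov_params())

    def fit(self, X: pd.DataFrame, y=None) -> "PooledLogisticGFormula":
        """Fit the pooled logistic hazard model on a prepped cohort."""
        c = self._compile(X)
        Xd, yd, wd = self._person_time_design(c)
        beta, cov = self._fit_arrays(Xd, yd, wd)
        self.term_names_ = self._term_names()
        self.coef_ = pd.Series(beta, index=self.term_names_)
        self.cov_params_ = cov
        self.converged_ = True
        self.n_events_ = int(yd.sum())
        self.n_person_years_ = int(len(yd))
        self._compiled_ = c
        return self

    def fit_person_time(self, pt: pd.DataFrame) -> "PooledLogisticGFormula":
        """Fit directly on a person-period table (columns ``t``, ``event``)."""
        self._check_params()
        diet_col = _DIET_COLUMN[self.diet]
        Xcov, _ = covariate_design(pt)
        tt, _ = time_design(pt["t"].to_numpy(float), self.time_degree)
        lead = pt["lead_log2"].to_numpy(float)
        ucd = pt["ucd_creat_log2"].to_numpy(float)
        diet = pt[diet_col].to_numpy(float)
        expo = [lead, ucd, diet]
        if self.include_interactions:
            expo += [lead * diet, ucd * diet]
        X = np.hstack([np.ones((len(pt), 1)), tt, np.column_stack(expo), Xcov])
        y = pt["event"].to_numpy(float)
        w = pt[self.weight_col].to_numpy(float)
        beta, cov = self._fit_arrays(X, y, w)
        self.term_names_ = self._term_names()
        self.coef_ = pd.Series(beta, index=self.term_names_)
        self.cov_params_ = cov
        self.converged_ = True
        self.n_events_ = int(y.sum())
        self.n_person_years_ = int(len(y))
        self._compiled_ = None
        return self

    # -- prediction --------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise ValueError("estimator is not fitted")

    def _split_beta(self, beta: np.ndarray):
        k = 1 + self.time_degree
        n_expo = 5 if self.include_interactions else 3
        return beta[0], beta[1:k], beta[k : k + n_expo], beta[k + n_expo :]

    def _base_lp(self, c: _Compiled, beta: np.ndarray) -> np.ndarray:
        b0, _, b_expo, b_cov = self._split_beta(beta)
        lp = b0 + c.Xcov @ b_cov
        lp += b_expo[0] * c.lead_log2 + b_expo[1] * c.ucd_log2 + b_expo[2] * c.diet
        if self.include_interactions:
            lp += b_expo[3] * c.lead_log2 * c.diet + b_expo[4] * c.ucd_log2 * c.diet
        return lp

    def _hazard_matrix(self, c: _Compiled, beta: np.ndarray) -> np.ndarray:
        _, b_time, _, _ = self._split_beta(beta)
        tt, _ = time_design(np.arange(1, self.horizon + 1), self.time_degree)
        return expit(self._base_lp(c, beta)[:, None] + (tt @ b_time)[None, :])

    def predict_hazard(self, cohort: pd.DataFrame) -> np.ndarray:
        """Fitted per-interval hazards, shape (n, horizon)."""
        self._check_fitted()
        return self._hazard_matrix(self._compile(cohort), self.coef_.to_numpy())

    def predict_individual_risk(self, cohort: pd.DataFrame, intervention: Intervention | None = None) -> np.ndarray:
        """Per-participant cumulative risk over the horizon, optionally intervened."""
        self._check_fitted()
        df = cohort
        if intervention is not None and not intervention.is_natural_course:
            df = apply_intervention(cohort, intervention, self.weight_col)
        return cumulative_risk(self.predict_hazard(df))

    def scenario_risk(self, cohort: pd.DataFrame, intervention: Intervention | None = None) -> float:
        """Survey-weighted mean counterfactual risk under an intervention.

        The identity (natural-course) intervention takes the same code path
        with no exposure modification, so it reproduces the natural-course
        risk exactly.
        """
        risks = self.predict_individual_risk(cohort, intervention)
        w = cohort[self.weight_col].to_numpy(float)
        return float(np.average(risks, weights=w))

    def scenario_risk_se(self, cohort: pd.DataFrame, intervention: Intervention | None = None) -> float:
        """Delta-method SE of the scenario risk from coefficient uncertainty.

        Ignores sampling of the standardization population and of percentile
        targets; useful as a quick model-based uncertainty scale (the
        bootstrap is the inferential tool).
        """
        self._check_fitted()
        df = cohort
        if intervention is not None and not intervention.is_natural_course:
            df = apply_intervention(cohort, intervention, self.weight_col)
        c = self._compile(df)
        beta = self.coef_.to_numpy()
        h = self._hazard_matrix(c, beta)  # (n, T)
        surv = np.prod(1.0 - h, axis=1)  # S_i
        w = c.w / c.w.sum()
        tt, _ = time_design(np.arange(1, self.horizon + 1), self.time_degree)
        # gradient of weighted mean risk wrt beta: sum_i w_i S_i sum_t h_it x_it
        coef_w = w * surv  # (n,)
        ht = h  # (n, T)
        grad = np.zeros(len(beta))
        # constant + cohort-level blocks share x across t: sum_t h_it factors out
        h_sum = ht.sum(axis=1)
        expo = [c.lead_log2, c.ucd_log2, c.diet]
        if self.include_interactions:
            expo += [c.lead_log2 * c.diet, c.ucd_log2 * c.diet]
        base_cols = [np.ones(c.n), *expo]
        k = 1 + self.time_degree
        n_expo = len(expo)
        grad[0] = coef_w @ (base_cols[0] * h_sum)
        for j in range(self.time_degree):
            grad[1 + j] = coef_w @ (ht @ tt[:, j])
        for j, col in enumerate(expo):
            grad[k + j] = coef_w @ (col * h_sum)
        grad[k + n_expo :] = (coef_w * h_sum) @ c.Xcov
        return float(np.sqrt(grad @ self.cov_params_ @ grad))

    # -- fast compiled path for the bootstrap ------------------------------

    def _compiled_scenario_risk(self, c: _Compiled, beta: np.ndarray, rules) -> float:
        """Scenario risk on a compiled cohort with pre-resolved rules.

        ``rules`` are (variable, mode, natural-scale target) triples.
        """
        cc = _Compiled(
            c.Xcov, c.lead_log2.copy(), c.ucd_log2.copy(), c.diet.copy(),
            c.lead_nat, c.ucd_nat, c.w, c.n_years, c.event_sel,
        )
        for var, mode, target in rules:
            if var == "blood_lead":
                arr, thr = cc.lead_log2, np.log2(target)
            elif var == "ucd_creat":
                arr, thr = cc.ucd_log2, np.log2(target)
            else:
                arr, thr = cc.diet, target
            if mode == "cap":
                np.minimum(arr, thr, out=arr)
            elif mode == "floor":
                np.maximum(arr, thr, out=arr)
            else:
                arr[:] = thr
        risks = 1.0 - np.prod(1.0 - self._hazard_matrix(cc, beta), axis=1)
        return float(np.average(risks, weights=c.w))

    def _resolve_compiled(self, c: _Compiled, scenarios: list[Intervention]) -> dict[str, list]:
        """Percentile targets from the compiled cohort's weighted distributions."""
        nat = {"blood_lead": c.lead_nat, "ucd_creat": c.ucd_nat, "dii": c.diet, "fv_servings": c.diet}
        out = {}
        for s in scenarios:
            rules = []
            for r in s.rules:
                if r.resolved:
                    rules.append((r.variable, r.mode, float(r.value)))
                else:
                    target = weighted_percentile(nat[r.variable], c.w, r.percentile)
                    rules.append((r.variable, r.mode, float(target)))
            out[s.name] = rules
        return out


# ---------------------------------------------------------------------------
# Functional wrappers and orchestration


def fit_pooled_logistic(pt: pd.DataFrame, **params) -> PooledLogisticGFormula:
    """Fit the pooled logistic hazard model on a person-period table."""
    return PooledLogisticGFormula(**params).fit_person_time(pt)


def estimate_scenario_risk(
    model: PooledLogisticGFormula,
    cohort: pd.DataFrame,
    intervention: Intervention | None = None,
    config: PrepConfig | None = None,
) -> float:
    """Counterfactual risk for one scenario from a fitted hazard model."""
    return model.scenario_risk(cohort, intervention)


def _boot_replicate(est: PooledLogisticGFormula, c: _Compiled, scenarios, start_beta, rng):
    idx = rng.integers(0, c.n, c.n)
    cb = c.take(idx)
    Xd, yd, wd = est._person_time_design(cb)
    beta, _ = est._fit_arrays(Xd, yd, wd, start=start_beta, compute_cov=False)
    resolved = est._resolve_compiled(cb, scenarios)
    return {name: est._compiled_scenario_risk(cb, beta, rules) for name, rules in resolved.items()}


def bootstrap_ci(
    cohort: pd.DataFrame,
    scenarios: list[Intervention],
    estimator: PooledLogisticGFormula,
    M: int = 200,
    seed: int = 0,
    references: tuple[str, ...] = ("natural course",),
    max_failure_fraction: float = 0.10,
) -> dict:
    """Percentile bootstrap of scenario risks and contrasts.

    Resamples whole participants with replacement (survey weights carried
    along), recomputes percentile targets, refits the hazard model and
    re-estimates every scenario risk per replicate; returns the replicate
    draws plus 2.5th/97.5th percentile bounds for risks, risk ratios and
    risk differences against each reference scenario. Deterministic given
    ``seed``; replicates that fail to converge are dropped and counted, and
    more than ``max_failure_fraction`` failures is an error.
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    est = estimator
    est._check_params()
    c = est._compile(cohort)
    Xd, yd, wd = est._person_time_design(c)
    start_beta, _ = est._fit_arrays(Xd, yd, wd)
    rng = substream(seed, f"bootstrap:{est.cause}:{est.diet}")
    draws: dict[str, list[float]] = {s.name: [] for s in scenarios}
    failures = 0
    for _ in range(M):
        try:
            risks = _boot_replicate(est, c, scenarios, start_beta, rng)
        except GFormulaError:
            failures += 1
            continue
        for name, r in risks.items():
            draws[name].append(r)
    if failures > max_failure_fraction * M:
        raise GFormulaError(f"{failures}/{M} bootstrap replicates failed to converge")
    risk_draws = {name: np.asarray(v) for name, v in draws.items()}
    out = {"risk_draws": risk_draws, "n_failures": failures, "M": M, "seed": seed, "ci": {}}
    for name, arr in risk_draws.items():
        out["ci"][name] = {"risk": _pctl(arr)}
        for ref in references:
            if ref not in risk_draws:
                continue
            if ref == name:
                # identity contrast: exactly RR 1, RD 0 in every replicate
                out["ci"][name][f"rr_vs_{ref}"] = (1.0, 1.0)
                out["ci"][name][f"rd_vs_{ref}"] = (0.0, 0.0)
                continue
            ref_arr = risk_draws[ref]
            rr = arr / ref_arr
            rd = (arr - ref_arr) * 100.0
            out["ci"][name][f"rr_vs_{ref}"] = _pctl(rr)
            out["ci"][name][f"rd_vs_{ref}"] = _pctl(rd)
    return out


def _pctl(arr: np.ndarray) -> tuple[float, float]:
    return float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5))


def run_gformula(
    cohort: pd.DataFrame,
    scenarios: list[Intervention],
    causes: tuple[str, ...] = ("all", "cvd", "cancer"),
    diet: str = "dii",
    M: int = 200,
    seed: int = 0,
    references: tuple[str, ...] = ("natural course", "worst case"),
    **estimator_params,
) -> pd.DataFrame:
    """End-to-end g-formula: fit, scenario risks, contrasts, bootstrap CIs.

    Returns one row per (cause, scenario, reference) with columns
    ``cause, scenario, reference, risk, risk_lo, risk_hi, rr, rr_lo, rr_hi,
    rd_pts, rd_lo, rd_hi, M, seed`` — risks as proportions, risk differences
    in percentage points. Point estimates come from the full cohort;
    interval bounds are bootstrap 2.5th/97.5th percentiles.
    """
    refs_present = [r for r in references if any(s.name == r for s in scenarios)]
    rows = []
    for cause in causes:
        est = PooledLogisticGFormula(cause=cause, diet=diet, **estimator_params)
        est.fit(cohort)
        point = {s.name: est.scenario_risk(cohort, s) for s in scenarios}
        boot = bootstrap_ci(cohort, scenarios, est, M=M, seed=seed, references=tuple(refs_present))
        for s in scenarios:
            for ref in refs_present:
                if s.name == ref:
                    rr, rd = 1.0, 0.0  # identity contrast, exact
                else:
                    rr, rd = contrast(point[s.name], point[ref])
                ci = boot["ci"][s.name]
                rr_ci = ci[f"rr_vs_{ref}"]
                rd_ci = ci[f"rd_vs_{ref}"]
                rows.append(
                    {
                        "cause": cause,
                        "scenario": s.name,
                        "reference": ref,
                        "risk": point[s.name],
                        "risk_lo": ci["risk"][0],
                        "risk_hi": ci["risk"][1],
                        "rr": rr,
                        "rr_lo": rr_ci[0],
                        "rr_hi": rr_ci[1],
                        "rd_pts": rd,
                        "rd_lo": rd_ci[0],
                        "rd_hi": rd_ci[1],
                        "M": M,
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)
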
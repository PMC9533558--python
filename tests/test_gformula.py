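"""Pooled logistic g-formula estimator, contrasts, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from dietmetals.gformula import (
    GFormulaError,
    PooledLogisticGFormula,
    bootstrap_ci,
    contrast,
    cumulative_risk,
    fit_pooled_logistic,
    run_gformula,
)
from dietmetals.interventions import Intervention, Rule, standard_scenarios
from dietmetals.prep import expand_person_time, prepare_cohort
from dietmetals.simulate import CohortConfig, TrueModel, generate_cohort


class TestCumulativeRisk:
    def test_closed_forms(self):
        assert cumulative_risk([0.1, 0.1, 0.1]) == pytest.approx(1 - 0.9**3)
        assert cumulative_risk([0.2, 1.0, 0.0]) == 1.0
        assert cumulative_risk([0.0, 0.0]) == 0.0

    def test_matrix_input_and_validation(self):
        out = cumulative_risk(np.array([[0.1, 0.2], [0.0, 0.0]]))
        assert out.shape == (2,)
        assert out[1] == 0.0
        with pytest.raises(ValueError):
            cumulative_risk([0.5, 1.2])

    def test_monotone_in_each_hazard(self):
        base = cumulative_risk([0.1, 0.2, 0.3])
        assert cumulative_risk([0.1, 0.25, 0.3]) > base
        assert cumulative_risk([0.1, 0.2, 0.3, 0.05]) > base


class TestContrast:
    def test_values_and_identity(self):
        rr, rd = contrast(0.02, 0.04)
        assert rr == pytest.approx(0.5)
        assert rd == pytest.approx(-2.0)
        assert contrast(0.3, 0.3) == (1.0, 0.0)

    def test_algebraic_consistency(self):
        ri, ref = 0.0588, 0.0588 / 1.72
        rr, rd = contrast(ri, ref)
        assert rr * ref == pytest.approx(ri, abs=1e-12)
        assert ref + rd / 100 == pytest.approx(ri, abs=1e-12)

    def test_zero_reference(self):
        with pytest.raises(ZeroDivisionError):
            contrast(0.1, 0.0)


class TestFit:
    def test_refit_reproduces_coefficients(self, prepped_medium):
        a = PooledLogisticGFormula().fit(prepped_medium).coef_
        b = PooledLogisticGFormula().fit(prepped_medium).coef_
        assert np.max(np.abs(a.to_numpy() - b.to_numpy())) <= 1e-8

    def test_person_time_path_matches_cohort_path(self, prepped_medium):
        via_cohort = PooledLogisticGFormula(cause="cvd").fit(prepped_medium).coef_
        pt = expand_person_time(prepped_medium, cause="cvd")
        via_pt = fit_pooled_logistic(pt, cause="cvd").coef_
        assert np.allclose(via_cohort.to_numpy(), via_pt.to_numpy(), atol=1e-8)

    def test_weight_invariance_under_duplication(self, prepped_small):
        half = prepped_small.copy()
        half["survey_weight"] = half["survey_weight"] / 2
        doubled = pd.concat([half, half], ignore_index=True)
        a = PooledLogisticGFormula().fit(prepped_small).coef_
        b = PooledLogisticGFormula().fit(doubled).coef_
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-6)

    def test_null_dgp_recovers_zero_exposure_effects(self):
        model = TrueModel.null()
        co = generate_cohort(CohortConfig(n_participants=4000, seed=31), model)
        prepped, _ = prepare_cohort(co)
        est = PooledLogisticGFormula().fit(prepped)
        se = np.sqrt(np.diag(est.cov_params_))
        for term in ("lead_log2", "ucd_creat_log2", "dii", "lead_log2:dii", "ucd_creat_log2:dii"):
            i = est.term_names_.index(term)
            assert abs(est.coef_[term]) < 3 * se[i], term

    def test_rank_deficiency_reported(self, prepped_small):
        co = prepped_small.copy()
        co["sex"] = "female"  # constant dummy column, collinear with intercept
        with pytest.raises(GFormulaError, match="rank"):
            PooledLogisticGFormula().fit(co)

    def test_no_events_rejected(self, prepped_small):
        co = prepped_small.copy()
        co["died"] = False
        co["cause"] = "none"
        with pytest.raises(GFormulaError, match="no events"):
            PooledLogisticGFormula().fit(co)

    def test_invalid_params_rejected(self, prepped_small):
        with pytest.raises(ValueError):
            PooledLogisticGFormula(cause="unknown").fit(prepped_small)
        with pytest.raises(ValueError):
            PooledLogisticGFormula(diet="keto").fit(prepped_small)


class TestStandardization:
    def test_identity_intervention_exact_natural_course(self, prepped_medium):
        est = PooledLogisticGFormula().fit(prepped_medium)
        nc = est.scenario_risk(prepped_medium)
        identity = est.scenario_risk(prepped_medium, Intervention("nc"))
        assert identity == nc  # same code path, bit for bit

    def test_natural_course_calibration(self):
        model = TrueModel.default()
        co = generate_cohort(
            CohortConfig(n_participants=4000, seed=37, admin_censor_range=(27.0, 27.0)), model
        )
        prepped, _ = prepare_cohort(co)
        est = PooledLogisticGFormula().fit(prepped)
        w = prepped["survey_weight"].to_numpy()
        wn = w / w.sum()
        emp = float(wn @ prepped["died"].to_numpy())
        se = np.sqrt(emp * (1 - emp) * float(wn @ wn))
        assert abs(est.scenario_risk(prepped) - emp) < 3 * se

    def test_capping_metal_lowers_risk(self, prepped_medium):
        est = PooledLogisticGFormula().fit(prepped_medium)
        assert est.coef_["lead_log2"] > 0  # harmful in this DGP
        nc = est.scenario_risk(prepped_medium)
        for p in (50, 25, 5):
            iv = Intervention("cap", (Rule("blood_lead", "cap", percentile=p),))
            assert est.scenario_risk(prepped_medium, iv) < nc

    def test_delta_se_positive_and_scaled(self, prepped_medium):
        est = PooledLogisticGFormula().fit(prepped_medium)
        se = est.scenario_risk_se(prepped_medium)
        assert 0 < se < 0.1


@pytest.fixture(scope="module")
def boot(prepped_medium):
    est = PooledLogisticGFormula()
    scen = standard_scenarios("dii")
    return bootstrap_ci(prepped_medium, scen, est, M=40, seed=3,
                        references=("natural course",))


class TestBootstrap:
    def test_deterministic_under_seed(self, prepped_medium, boot):
        est = PooledLogisticGFormula()
        scen = standard_scenarios("dii")
        again = bootstrap_ci(prepped_medium, scen, est, M=40, seed=3,
                             references=("natural course",))
        for name in boot["ci"]:
            assert boot["ci"][name] == again["ci"][name]

    def test_identity_contrast_degenerate_ci(self, boot):
        nc = boot["ci"]["natural course"]
        assert nc["rr_vs_natural course"] == (1.0, 1.0)
        assert nc["rd_vs_natural course"] == (0.0, 0.0)

    def test_ci_orders_and_content(self, boot):
        for name, ci in boot["ci"].items():
            lo, hi = ci["risk"]
            assert 0 <= lo <= hi <= 1

    def test_ci_width_shrinks_with_n(self, default_model):
        widths = {}
        for n, seed in ((1000, 41), (4000, 43)):
            co = generate_cohort(CohortConfig(n_participants=n, seed=seed), default_model)
            prepped, _ = prepare_cohort(co)
            est = PooledLogisticGFormula()
            scen = standard_scenarios("dii")
            boot = bootstrap_ci(prepped, scen, est, M=60, seed=5,
                                references=("natural course",))
            lo, hi = boot["ci"]["lower both metals"]["rr_vs_natural course"]
            widths[n] = hi - lo
        assert widths[4000] < widths[1000]

    def test_m_validation(self, prepped_small):
        with pytest.raises(ValueError):
            bootstrap_ci(prepped_small, standard_scenarios("dii"), PooledLogisticGFormula(), M=1)


@pytest.fixture(scope="module")
def results(prepped_medium):
    scen = standard_scenarios("dii")
    return run_gformula(
        prepped_medium, scen, causes=("all", "cvd"), M=12, seed=9,
        references=("natural course", "worst case"),
    )


class TestRunGFormula:
    def test_shape_contract(self, results):
        # causes x scenarios x references
        assert len(results) == 2 * 7 * 2

    def test_natural_course_identity_row(self, results):
        row = results[(results.scenario == "natural course") & (results.reference == "natural course")].iloc[0]
        assert row["rr"] == 1.0
        assert row["rd_pts"] == 0.0

    def test_deterministic_rerun(self, prepped_medium, results):
        scen = standard_scenarios("dii")
        again = run_gformula(
            prepped_medium, scen, causes=("all", "cvd"), M=12, seed=9,
            references=("natural course", "worst case"),
        )
        pd.testing.assert_frame_equal(results, again)

    def test_contrast_algebra_in_rows(self, results):
        nc = results[(results.cause == "all") & (results.scenario == "natural course")
                     & (results.reference == "natural course")].iloc[0]["risk"]
        sub = results[(results.cause == "all") & (results.reference == "natural course")]
        for _, row in sub.iterrows():
            assert row["rr"] * nc == pytest.approx(row["risk"], abs=1e-12)
            assert nc + row["rd_pts"] / 100 == pytest.approx(row["risk"], abs=1e-12)
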
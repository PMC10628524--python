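"""Mixed models, robust regressions, demographic tests and the alpha policy."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from megsw import (
    ValidationError,
    chi_square_2x2,
    fit_reactivity_regression,
    fit_recall_regression,
    fit_sw_mixed_model,
    significance_policy,
    two_sample_t_from_summary,
)
from megsw.core import ModelResult
from megsw.simulate import SubjectTableSpec, generate_reactivity_table, generate_subject_table


def _table(seed=0, **kwargs):
    defaults = dict(
        n_per_group=(60, 40), beta_disease=-0.1, beta_condition=0.03, beta_age=0.01,
        sigma_subject=0.1, sigma_resid=0.08, bands=("gamma",),
    )
    defaults.update(kwargs)
    return generate_subject_table(SubjectTableSpec(seed=seed, **defaults))


class TestMixedModel:
    def test_condition_coding_flip_negates_coefficient(self):
        table = _table(seed=1)
        res = fit_sw_mixed_model(table, "gamma")
        flipped = table.copy()
        flipped["condition"] = flipped["condition"].map({"EO": "EC", "EC": "EO"})
        res_f = fit_sw_mixed_model(flipped, "gamma")
        i = res.terms.index("condition")
        assert res_f.coefficients[i] == pytest.approx(-res.coefficients[i], rel=1e-6)
        assert abs(res_f.statistic[i]) == pytest.approx(abs(res.statistic[i]), rel=1e-6)

    def test_row_shuffle_invariance(self):
        table = _table(seed=2)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = fit_sw_mixed_model(table, "gamma")
        b = fit_sw_mixed_model(shuffled, "gamma")
        np.testing.assert_allclose(a.coefficients, b.coefficients, rtol=1e-6)

    def test_zero_between_subject_variance_matches_pooled_ols(self):
        table = _table(seed=4, n_per_group=(300, 200), sigma_subject=0.0)
        res = fit_sw_mixed_model(table, "gamma")
        sl = table[table["band"] == "gamma"]
        X = np.column_stack(
            [
                np.ones(len(sl)),
                (sl["group"] == "AD").astype(float),
                (sl["condition"] == "EO").astype(float),
                sl["age"],
            ]
        )
        ols = sm.OLS(sl["sw"].to_numpy(), X).fit()
        assert np.max(np.abs(res.coefficients - ols.params)) < 1e-4

    def test_boundary_variance_fit_is_flagged(self):
        # within-subject values anti-correlated around zero subject means:
        # the ML between-subject variance pins to the boundary at 0
        rng = np.random.default_rng(0)
        n = 40
        e = rng.normal(0, 1, n)
        rows = []
        for i in range(n):
            for cond, sign in (("EO", 1.0), ("EC", -1.0)):
                rows.append(
                    {
                        "subject_id": f"s{i}",
                        "group": "AD" if i % 2 else "control",
                        "condition": cond,
                        "age": 70.0 + (i % 7),
                        "delayed_recall": 80.0,
                        "band": "gamma",
                        "sw": 1.0 + sign * e[i],
                    }
                )
        res = fit_sw_mixed_model(pd.DataFrame(rows), "gamma")
        assert "boundary_random_effect" in res.flags

    def test_robust_and_model_ses_agree_when_homoscedastic(self):
        table = _table(seed=5, n_per_group=(150, 100))
        robust = fit_sw_mixed_model(table, "gamma")
        model = fit_sw_mixed_model(table, "gamma", se_flavor="model-based")
        ratio = robust.robust_se / model.robust_se
        assert np.all((ratio > 0.85) & (ratio < 1.15))

    def test_statistic_is_coefficient_over_se(self):
        res = fit_sw_mixed_model(_table(seed=6), "gamma")
        np.testing.assert_allclose(
            res.statistic, res.coefficients / res.robust_se, atol=1e-10
        )

    def test_requires_both_conditions(self):
        table = _table(seed=7, conditions=("EO",))
        with pytest.raises(ValidationError, match="condition"):
            fit_sw_mixed_model(table, "gamma")


class TestRecallRegression:
    def test_linear_reparameterization_invariance(self):
        table = _table(seed=8, beta_recall=-0.01, bands=("alpha",), conditions=("EO",))
        res = fit_recall_regression(table, "alpha", "control", "EO")
        rescaled = table.copy()
        rescaled["delayed_recall"] = rescaled["delayed_recall"] * 10
        res_r = fit_recall_regression(rescaled, "alpha", "control", "EO")
        i = res.terms.index("delayed_recall")
        assert res_r.coefficients[i] == pytest.approx(res.coefficients[i] / 10, rel=1e-9)
        assert res_r.statistic[i] == pytest.approx(res.statistic[i], rel=1e-9)

    def test_recovers_generating_slope(self):
        spec = SubjectTableSpec(
            n_per_group=(4, 100), beta_recall=-0.013, beta_age=0.032,
            sigma_subject=0.0, sigma_resid=0.1, bands=("alpha",), conditions=("EO",), seed=9,
        )
        res = fit_recall_regression(generate_subject_table(spec), "alpha", "AD", "EO")
        assert res.term("delayed_recall")["coefficient"] == pytest.approx(-0.013, abs=0.004)

    def test_eta_squared_between_zero_and_one(self):
        res = fit_recall_regression(_table(seed=10, bands=("alpha",)), "alpha", "control", "EO")
        assert np.all((res.effect_size >= 0) & (res.effect_size <= 1))

    def test_tiny_slice_rejected(self):
        table = _table(seed=11, n_per_group=(3, 3), bands=("alpha",))
        with pytest.raises(ValidationError, match="insufficient"):
            fit_recall_regression(table, "alpha", "control", "EO")


class TestReactivityRegression:
    def test_degenerate_constant_outcome_flagged(self):
        spec = SubjectTableSpec(n_per_group=(10, 10), intercept=0.0, sigma_resid=0.0, seed=12)
        table = generate_reactivity_table(spec)
        res = fit_reactivity_regression(table, "alpha", "control")
        assert "degenerate_constant_outcome" in res.flags
        assert res.term("delayed_recall")["coefficient"] == 0.0

    def test_subject_order_invariance(self):
        spec = SubjectTableSpec(
            n_per_group=(30, 30), intercept=0.0, beta_recall=-0.006, sigma_resid=0.05, seed=13
        )
        table = generate_reactivity_table(spec)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = fit_reactivity_regression(table, "alpha", "AD")
        b = fit_reactivity_regression(shuffled, "alpha", "AD")
        np.testing.assert_allclose(a.coefficients, b.coefficients, rtol=1e-9)

    def test_duplicate_subject_rows_rejected(self):
        spec = SubjectTableSpec(n_per_group=(10, 10), intercept=0.0, seed=14)
        table = generate_reactivity_table(spec)
        alpha_ctrl = table[(table["band"] == "alpha") & (table["group"] == "control")]
        dup = pd.concat([table, alpha_ctrl.iloc[:2]], ignore_index=True)
        with pytest.raises(ValidationError, match="one reactivity row"):
            fit_reactivity_regression(dup, "alpha", "control")


class TestGroupComparisons:
    def test_pooled_t_matches_direct_formula(self):
        cmp = two_sample_t_from_summary(10.0, 2.0, 12, 8.0, 3.0, 10, variable="x")
        sp2 = (11 * 4 + 9 * 9) / 20
        expected = 2.0 / np.sqrt(sp2 * (1 / 12 + 1 / 10))
        assert cmp.statistic == pytest.approx(expected)
        assert cmp.df == 20

    def test_identical_groups(self):
        cmp = two_sample_t_from_summary(5.0, 0.0, 10, 5.0, 0.0, 10)
        assert cmp.statistic == 0.0 and cmp.p_value == 1.0

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValidationError, match="pooled variance"):
            two_sample_t_from_summary(5.0, 0.0, 10, 6.0, 0.0, 10)

    def test_proportional_table_chi2_zero(self):
        assert chi_square_2x2(10, 10, 5, 5).statistic == pytest.approx(0.0)

    def test_diagonal_table_closed_form(self):
        # hand-check: chi2 = n (ad-bc)^2 / (r1 r2 c1 c2) = 40*(400)^2/(20^4) = 40
        assert chi_square_2x2(20, 0, 0, 20).statistic == pytest.approx(40.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError, match="margin"):
            chi_square_2x2(0, 0, 5, 5)


class TestSignificancePolicy:
    def _result(self, p):
        k = 1
        arr = np.array([p])
        one = np.array([1.0])
        return ModelResult(
            outcome="sw", terms=["x"], coefficients=one, robust_se=one,
            statistic=one, p_value=arr, effect_size=one, n_obs=10, n_subjects=10,
            se_flavor="heteroscedasticity-robust", alpha_threshold=0.05,
        )

    def test_mixed_family_threshold(self):
        res = significance_policy([self._result(0.031)], "mixed")[0]
        assert res.significant[0]

    def test_regression_family_threshold(self):
        res = significance_policy([self._result(0.029)], "regression")[0]
        assert not res.significant[0]

    def test_boundary_is_strict(self):
        res = significance_policy([self._result(0.025)], "reactivity")[0]
        assert not res.significant[0]

    def test_unknown_family_rejected(self):
        with pytest.raises(ValidationError, match="analysis_family"):
            significance_policy([], "anova")
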
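"""First-principles statistics vs hand-derived values and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cephalomine import (
    CollinearityError,
    GeneratorConfig,
    StatisticError,
    generate_cohort,
    ols_fit,
    screen_variables,
    spearman_rho,
    two_sample_t,
)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]).estimate == 1.0
        assert spearman_rho([1, 2, 3], [3, 2, 1]).estimate == -1.0

    def test_tied_ranks_hand_value(self):
        # ranks of x=(1,2,2,4) are (1, 2.5, 2.5, 4); of y=(1,3,2,4) are
        # (1,3,2,4); Pearson on those ranks gives 4.5/sqrt(4.5*5) = 3/sqrt(10)
        r = spearman_rho([1, 2, 2, 4], [1, 3, 2, 4])
        assert r.estimate == pytest.approx(3 / np.sqrt(10), abs=1e-12)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 10, size=60).astype(float)
        y = rng.integers(0, 10, size=60).astype(float)
        ref = stats.spearmanr(x, y)
        ours = spearman_rho(x, y)
        assert ours.estimate == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    @pytest.mark.parametrize(
        "x,y",
        [([1, 2], [3, 4]), ([1, 2, 3], [5, 5, 5]), ([1, 2, 3], [1, 2])],
    )
    def test_undefined_cases_raise(self, x, y):
        with pytest.raises(StatisticError):
            spearman_rho(x, y)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-1e6, 1e6, allow_nan=False),
                st.floats(-1e6, 1e6, allow_nan=False),
            ),
            min_size=4,
            max_size=40,
        )
    )
    def test_monotone_transform_invariance(self, data):
        x = np.array([d[0] for d in data])
        y = np.array([d[1] for d in data])
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        base = spearman_rho(x, y).estimate
        # strictly monotone transform, exact in floating point: map each
        # value to the cube of its position in the sorted unique values
        positions = np.searchsorted(np.unique(x), x).astype(float)
        transformed = spearman_rho(positions**3 + 5.0, y).estimate
        assert transformed == pytest.approx(base, abs=1e-9)


class TestTTest:
    def test_identical_groups_t_zero(self):
        r = two_sample_t([1, 2, 3], [1, 2, 3])
        assert r.estimate == 0.0
        assert r.p_value == 1.0

    def test_pooled_formula_hand_value(self):
        # means 2 and 5, both variances 1, pooled s²=1,
        # t = -3 / sqrt(1·(1/3+1/3)) = -3·sqrt(3/2)
        r = two_sample_t([1, 2, 3], [4, 5, 6])
        assert r.estimate == pytest.approx(-3 * np.sqrt(1.5), abs=1e-12)
        ref = stats.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=True)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.3, 2, 20)
        r = two_sample_t(a, b, welch=True)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert r.estimate == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_sign_flips_on_swap(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 25)
        assert two_sample_t(a, b).estimate == pytest.approx(
            -two_sample_t(b, a).estimate, abs=1e-12
        )

    def test_small_group_raises(self):
        with pytest.raises(StatisticError):
            two_sample_t([1], [2, 3])

    def test_zero_variance_equal_means(self):
        r = two_sample_t([2, 2], [2, 2])
        assert (r.estimate, r.p_value) == (0.0, 1.0)


class TestOLS:
    def test_exact_fit(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        results = ols_fit(2 * x + 1, {"x": x})
        by_name = {r.variable: r for r in results}
        assert by_name["intercept"].estimate == pytest.approx(1.0, abs=1e-10)
        assert by_name["x"].estimate == pytest.approx(2.0, abs=1e-10)

    def test_duplicated_column_collinearity(self):
        x = np.arange(8.0)
        with pytest.raises(CollinearityError, match="x2"):
            ols_fit(x * 3, {"x1": x, "x2": x})

    def test_normal_equations_oracle(self):
        # 6-point bivariate: solve (XᵀX)⁻¹Xᵀy by explicit inversion
        x1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        x2 = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        y = np.array([3.1, 3.9, 7.2, 7.8, 11.1, 11.9])
        X = np.column_stack([np.ones(6), x1, x2])
        beta_hand = np.linalg.inv(X.T @ X) @ X.T @ y
        results = ols_fit(y, {"x1": x1, "x2": x2})
        estimates = np.array([r.estimate for r in results])
        assert estimates == pytest.approx(beta_hand, abs=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        y = 1 + X["a"] * 2 - X["b"] + rng.normal(size=40)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        ours = {r.variable: r for r in ols_fit(y, X)}
        for name, ref_name in [("intercept", "const"), ("a", "a"), ("b", "b"), ("c", "c")]:
            assert ours[name].estimate == pytest.approx(ref.params[ref_name], abs=1e-10)
            assert ours[name].p_value == pytest.approx(ref.pvalues[ref_name], rel=1e-8)
            lo, hi = ref.conf_int().loc[ref_name]
            assert ours[name].ci_low == pytest.approx(lo, abs=1e-9)
            assert ours[name].ci_high == pytest.approx(hi, abs=1e-9)

    def test_residuals_orthogonal_to_predictors(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        y = rng.normal(size=60)
        results = {r.variable: r.estimate for r in ols_fit(y, X)}
        beta = np.array([results["intercept"], *[results[c] for c in "abcd"]])
        design = np.column_stack([np.ones(60), X.to_numpy()])
        resid = y - design @ beta
        assert np.abs(design.T @ resid).max() < 1e-8

    def test_insufficient_n(self):
        with pytest.raises(StatisticError):
            ols_fit([1.0, 2.0], {"x": [1.0, 2.0]})


class TestScreen:
    def test_default_cohort_flags_expected_variables(self, default_cohort):
        report = screen_variables(default_cohort)
        assert {"brain_volume_ml", "sex_female", "height_cm"} <= report.significant

    def test_null_effects_rarely_flagged(self):
        # with no sex offset and no height slope, sex and height should be
        # declared non-significant in at least 90% of seeds
        hits = 0
        for seed in range(20):
            cfg = GeneratorConfig(
                n_subjects=2000,
                seed=seed,
                hc_height_slope_cm_per_m=0.0,
                hc_male_offset_cm=0.0,
            )
            report = screen_variables(generate_cohort(cfg))
            if not {"sex_female", "height_cm"} & report.significant:
                hits += 1
        assert hits >= 18

    def test_tiny_cohort_raises(self):
        cohort = generate_cohort(GeneratorConfig(n_subjects=3, seed=0))
        with pytest.raises(StatisticError):
            screen_variables(cohort)

    def test_report_serialisable(self, default_cohort):
        import json

        payload = screen_variables(default_cohort).to_dict()
        text = json.dumps(payload)
        assert "spearman" in text and "ols" in text
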
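import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swimassay import (
    RepeatedMeasures,
    intertest_correlation,
    repeatability,
    summarise,
    variance_components,
)
from swimassay.synth import simulate_repeated


def rm(rows, columns=None, endpoint="e"):
    df = pd.DataFrame(rows, columns=columns)
    df.index = [f"s{i}" for i in range(len(df))]
    return RepeatedMeasures(values=df, endpoint=endpoint)


class TestVarianceComponents:
    def test_hand_anova_2x2(self):
        """Subjects {(0,2),(4,6)}: MS_b 16, MS_w 2 -> var_b 7, var_w 2."""
        vb, vw = variance_components(rm([[0, 2], [4, 6]]))
        assert vb == pytest.approx(7.0, abs=1e-12)
        assert vw == pytest.approx(2.0, abs=1e-12)

    def test_zero_residual(self):
        """Constant subject profiles: all variance is between subjects."""
        vb, vw = variance_components(rm([[1, 1], [3, 3]]))
        assert vw == 0.0
        assert vb == pytest.approx(2.0, abs=1e-12)

    def test_negative_between_truncated(self):
        """Identical subject profiles: between-subject estimate floored at 0."""
        vb, vw = variance_components(rm([[1, 3], [1, 3]]))
        assert vb == 0.0
        assert vw == pytest.approx(2.0)

    def test_unbalanced_design(self):
        """Missing cells use the unbalanced design coefficient k0."""
        data = rm([[0, 2, np.nan], [4, 6, 5], [1, 2, 3]])
        vb, vw = variance_components(data)
        # independent check via the classical formulas
        groups = [np.array([0.0, 2]), np.array([4.0, 6, 5]),
                  np.array([1.0, 2, 3])]
        N = sum(len(g) for g in groups)
        n = len(groups)
        grand = np.concatenate(groups).mean()
        msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (N - n)
        msb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups) / (n - 1)
        k0 = (N - sum(len(g) ** 2 for g in groups) / N) / (n - 1)
        assert vw == pytest.approx(msw, abs=1e-12)
        assert vb == pytest.approx(max(0, (msb - msw) / k0), abs=1e-12)

    def test_single_subject_raises(self):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            variance_components(rm([[1, 2]]))

    def test_single_observation_subjects_excluded(self):
        data = rm([[0, 2], [4, 6], [9, np.nan]])
        with pytest.warns(UserWarning, match="excluding 1 subject"):
            vb, vw = variance_components(data)
        assert (vb, vw) == (pytest.approx(7.0), pytest.approx(2.0))

    def test_matches_reml_on_balanced_gaussian_data(self):
        """Method-of-moments agrees with the mixed-model (REML) estimator
        on balanced data — independent cross-check via statsmodels."""
        import statsmodels.formula.api as smf

        d = simulate_repeated(10.0, 1.0, 1.0, 40, 3, seed=77)
        vb, vw = variance_components(d)
        long = d.values.reset_index().melt(
            id_vars="subject_id", var_name="session", value_name="y"
        )
        fit = smf.mixedlm("y ~ 1", long, groups=long["subject_id"]).fit(
            reml=True
        )
        assert vb == pytest.approx(float(fit.cov_re.iloc[0, 0]), rel=1e-3)
        assert vw == pytest.approx(float(fit.scale), rel=1e-3)


class TestRepeatability:
    def test_hand_example_r(self):
        est = repeatability(rm([[0, 2], [4, 6]]), n_boot=0)
        assert est.r == pytest.approx(7.0 / 9.0, abs=1e-12)

    def test_zero_within_variance_gives_r_one(self):
        est = repeatability(rm([[1, 1], [3, 3]]), n_boot=0)
        assert est.r == 1.0

    def test_simulated_half_repeatability(self):
        """var_b = var_e = 1, n = 100, k = 3: mean R-hat over seeded
        datasets lands in [0.45, 0.55] around the true 0.5."""
        rs = [repeatability(
            simulate_repeated(0.0, 1.0, 1.0, 100, 3, seed=42 + s),
            n_boot=0).r for s in range(40)]
        assert 0.45 <= np.mean(rs) <= 0.55

    def test_bootstrap_is_seed_deterministic(self):
        d = simulate_repeated(0.0, 1.0, 1.0, 30, 3, seed=8)
        e1 = repeatability(d, n_boot=500, seed=99)
        e2 = repeatability(d, n_boot=500, seed=99)
        assert (e1.ci_low, e1.ci_high) == (e2.ci_low, e2.ci_high)

    def test_degenerate_zero_variance(self):
        with pytest.warns(UserWarning, match="zero total variance"):
            est = repeatability(rm([[5, 5], [5, 5]]), n_boot=100)
        assert est.r == 0.0 and (est.ci_low, est.ci_high) == (0.0, 0.0)
        assert est.significant is False

    def test_significance_flag_tracks_ci(self):
        strong = simulate_repeated(0.0, 2.0, 0.5, 50, 3, seed=3)
        est = repeatability(strong, n_boot=300, seed=1)
        assert est.significant is True and est.ci_low > 0

    def test_bootstrap_ci_bounds_ordered_within_unit_interval(self):
        d = simulate_repeated(0.0, 1.0, 1.0, 30, 3, seed=12)
        est = repeatability(d, n_boot=300, seed=5)
        assert 0.0 <= est.ci_low <= est.ci_high <= 1.0

    @given(a=st.floats(0.1, 10), b=st.floats(-50, 50))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance_of_r(self, a, b):
        """R is unchanged by y -> a*y + b."""
        d = simulate_repeated(0.0, 1.0, 1.0, 20, 3, seed=31)
        r0 = repeatability(d, n_boot=0).r
        d2 = RepeatedMeasures(values=a * d.values + b, endpoint="e")
        assert repeatability(d2, n_boot=0).r == pytest.approx(r0, abs=1e-9)

    def test_monotone_in_true_between_variance(self):
        """Holding var_within, higher true var_between raises mean R-hat."""
        means = []
        for sb in (0.5, 1.0, 2.0):
            rs = [repeatability(
                simulate_repeated(0.0, sb, 1.0, 50, 3, seed=100 * s + 7),
                n_boot=0).r for s in range(30)]
            means.append(np.mean(rs))
        assert means[0] < means[1] < means[2]

    def test_bootstrap_ci_coverage_near_nominal(self):
        """95% parametric-bootstrap CI covers the true R about 95% of the
        time under the generating random-intercept model."""
        true_r = 0.5
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            d = simulate_repeated(0.0, 1.0, 1.0, 100, 3, seed=5000 + s)
            est = repeatability(d, n_boot=1000, seed=s)
            hits += est.ci_low <= true_r <= est.ci_high
        assert 0.90 <= hits / n_rep <= 0.99


class TestSummaries:
    def test_sim_and_sum(self):
        d = rm([[2, 4, 6]], columns=["s1", "s2", "s3"])
        assert summarise(d, "SuM").iloc[0] == pytest.approx(4.0)
        assert summarise(d, "SiM").iloc[0] == pytest.approx(2.0)

    def test_sum_with_missing_session(self):
        d = rm([[1, np.nan, 3]], columns=["s1", "s2", "s3"])
        assert summarise(d, "SuM").iloc[0] == pytest.approx(2.0)

    def test_empty_subject_excluded_with_warning(self):
        d = rm([[1, 2], [np.nan, np.nan]], columns=["s1", "s2"])
        with pytest.warns(UserWarning, match="excluding"):
            out = summarise(d, "SuM")
        assert len(out) == 1


class TestIntertestCorrelation:
    def test_perfect_linear_pearson(self):
        x = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        r, p, n = intertest_correlation(x, 2 * x + 1, "pearson")
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_monotone_nonlinear_spearman_vs_pearson(self):
        x = pd.Series([-2.0, -1, 0, 1, 2], index=list("abcde"))
        y = x**3
        rs, _, _ = intertest_correlation(x, y, "spearman")
        rp, _, _ = intertest_correlation(x, y, "pearson")
        assert rs == pytest.approx(1.0)
        assert rp < 1.0

    def test_independent_vectors_near_zero(self):
        rng1 = np.random.default_rng(1)
        rng2 = np.random.default_rng(2)
        idx = [f"s{i}" for i in range(1000)]
        x = pd.Series(rng1.normal(size=1000), index=idx)
        y = pd.Series(rng2.normal(size=1000), index=idx)
        r, _, _ = intertest_correlation(x, y, "pearson")
        assert abs(r) < 0.1

    def test_pairs_matched_by_subject_id(self):
        x = pd.Series([1.0, 2, 3], index=["a", "b", "c"])
        y = pd.Series([30.0, 10, 20], index=["c", "a", "b"])
        r, _, n = intertest_correlation(x, y, "pearson")
        assert r == pytest.approx(1.0) and n == 3

    def test_zero_variance_returns_nan(self):
        x = pd.Series([1.0, 1, 1], index=list("abc"))
        y = pd.Series([1.0, 2, 3], index=list("abc"))
        with pytest.warns(UserWarning, match="zero variance"):
            r, p, n = intertest_correlation(x, y)
        assert np.isnan(r)

    def test_too_few_pairs_raises(self):
        x = pd.Series([1.0, 2], index=["a", "b"])
        with pytest.raises(ValueError, match=">= 3"):
            intertest_correlation(x, x)
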
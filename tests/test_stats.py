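"""Assumption checks, nonparametric tests, Box-Cox and the factorial model."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nirpulse.stats import (
    boxcox_transform,
    check_assumptions,
    factorial_anova,
    feature_statistics,
    kruskal_wallis,
    mann_whitney_u,
)


class TestCheckAssumptions:
    def test_identical_groups_bartlett_zero(self, rng):
        g = rng.normal(size=50)
        results = check_assumptions({"a": g, "b": g.copy()})
        bart = next(r for r in results if r.test == "bartlett")
        assert bart.statistic == pytest.approx(0.0, abs=1e-12)
        assert bart.p_value == pytest.approx(1.0)

    def test_constant_group_flagged_nan(self, rng):
        results = check_assumptions({"a": np.full(10, 2.0), "b": rng.normal(size=10)})
        flagged = [r for r in results if r.group == "a"]
        assert all(np.isnan(r.p_value) and r.note for r in flagged)
        assert all(not r.significant for r in flagged)

    def test_unequal_variances_detected(self, rng):
        a = rng.normal(scale=1.0, size=60)
        b = rng.normal(scale=3.0, size=60)
        bart = next(r for r in check_assumptions({"a": a, "b": b}) if r.test == "bartlett")
        assert bart.p_value < 0.01

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            check_assumptions({"a": np.array([1.0, 2.0])})


def exact_mw_pvalue(a, b):
    """Enumeration oracle: two-sided p over all group labelings (no ties)."""
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_stat(idx_a):
        ranks = np.argsort(np.argsort(pooled)) + 1
        r_a = ranks[list(idx_a)].sum()
        return r_a - n_a * (n_a + 1) / 2

    observed = u_stat(range(n_a))
    mean_u = n_a * len(b) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_stat(combo) - mean_u) >= abs(observed - mean_u) - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_samples(self, rng):
        a = rng.normal(size=10)
        res = mann_whitney_u(a, a.copy())
        assert res.statistic == pytest.approx(50.0)  # n^2 / 2
        assert res.p_value > 0.9

    def test_separated_groups_exact(self):
        res = mann_whitney_u(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert res.statistic in (0.0, 9.0)
        assert res.p_value == pytest.approx(0.1)  # 2/20 labelings as extreme

    def test_matches_enumeration_oracle(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(loc=0.7, size=6)
        res = mann_whitney_u(a, b)
        assert res.p_value == pytest.approx(exact_mw_pvalue(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u(np.array([]), np.array([1.0]))

    def test_shift_alternative_power(self, rng):
        rejections = 0
        reps = 100
        for _ in range(reps):
            a = rng.normal(size=50)
            b = rng.normal(loc=1.5, size=50)
            if mann_whitney_u(a, b).p_value < 0.05:
                rejections += 1
        assert rejections / reps >= 0.8


class TestKruskalWallis:
    def test_two_groups_agree_with_mann_whitney(self, rng):
        a = rng.normal(size=50)
        b = rng.normal(loc=0.3, size=50)
        kw = kruskal_wallis({"a": a, "b": b})
        mw = mann_whitney_u(a, b)
        assert kw.p_value == pytest.approx(mw.p_value, abs=0.02)

    def test_all_identical_values(self):
        res = kruskal_wallis({"a": np.full(5, 1.0), "b": np.full(5, 1.0)})
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_shifted_group_detected(self, rng):
        hits = 0
        for _ in range(20):
            groups = {
                "a": rng.normal(size=30),
                "b": rng.normal(size=30),
                "c": rng.normal(loc=2.0, size=30),
            }
            hits += kruskal_wallis(groups).p_value < 0.05
        assert hits >= 19

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": np.array([1.0])})


class TestBoxCox:
    def test_lambda_one_is_shifted_identity(self):
        x = np.linspace(1.0, 5.0, 20)
        fit = boxcox_transform(x)
        lam1 = type(fit)(lambda_opt=1.0, shift=fit.shift, transformed=None)
        np.testing.assert_allclose(lam1.apply(x), x + fit.shift - 1.0, rtol=1e-12)

    def test_negative_data_shifted_positive(self, rng):
        x = rng.normal(loc=-10.0, size=50)
        fit = boxcox_transform(x)
        assert np.all(x + fit.shift > 0)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            boxcox_transform(np.full(20, 3.0))

    @given(st.integers(0, 10_000))
    def test_monotone(self, seed):
        x = np.random.default_rng(seed).gamma(2.0, size=30)
        fit = boxcox_transform(x)
        order = np.argsort(x)
        assert np.all(np.diff(fit.transformed[order]) >= 0)


def balanced_table(rng, n_per_cell=30, condition_shift=0.0):
    rows = []
    for cond in ("supine", "trendelenburg"):
        for det in ("distal", "proximal"):
            shift = condition_shift if cond == "trendelenburg" else 0.0
            for v in rng.normal(loc=shift, size=n_per_cell):
                rows.append({"y": v, "condition": cond, "detector": det})
    return pd.DataFrame(rows)


class TestFactorialAnova:
    def test_balanced_type2_equals_type1(self, rng):
        # balance makes Type II and Type I sums of squares coincide
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = balanced_table(rng)
        res = factorial_anova(df, "y", boxcox="never")
        model = smf.ols("y ~ C(condition) * C(detector)", data=df).fit()
        t1 = sm.stats.anova_lm(model, typ=1)
        assert res.terms["condition"][0] == pytest.approx(t1.loc["C(condition)", "F"])
        assert res.terms["detector"][0] == pytest.approx(t1.loc["C(detector)", "F"])

    def test_condition_effect_detected_interaction_null(self, rng):
        df = balanced_table(rng, n_per_cell=40, condition_shift=1.0)
        res = factorial_anova(df, "y", boxcox="never")
        assert res.p_value("condition") < 0.05
        assert res.terms["condition:detector"][1] > 0.001  # no injected interaction

    def test_empty_cell_named(self, rng):
        df = balanced_table(rng)
        df = df[~((df.condition == "supine") & (df.detector == "proximal"))]
        with pytest.raises(ValueError, match="supine.*proximal"):
            factorial_anova(df, "y", boxcox="never")

    def test_boxcox_auto_transforms_skewed_response(self, rng):
        df = balanced_table(rng, n_per_cell=60)
        df["y"] = np.exp(df["y"])  # lognormal: assumptions fail
        res = factorial_anova(df, "y", boxcox="auto")
        assert res.boxcox_lambda is not None

    def test_single_level_factor_rejected(self, rng):
        df = balanced_table(rng)
        with pytest.raises(ValueError, match="levels"):
            factorial_anova(df[df.detector == "distal"], "y", boxcox="never")


class TestFeatureStatistics:
    def _table(self, rng, effect=1.0):
        rows = []
        for subject in ("s1", "s2", "s3"):
            for det in ("distal", "proximal"):
                for cond, mult in (
                    ("supine1", 1.0), ("supine2", 1.0), ("trendelenburg", effect)
                ):
                    for w in range(8):
                        feats = {
                            f"f{i}": mult * (1 + 0.1 * rng.normal()) for i in range(1, 10)
                        }
                        rows.append(
                            dict(subject=subject, intervention="tilting",
                                 condition=cond, detector=det, wavelength_nm=810,
                                 window_index=w, **feats)
                        )
        return pd.DataFrame(rows)

    def test_report_shape_and_flags(self, rng):
        out = feature_statistics(self._table(rng), "tilting", boxcox="never")
        # 9 features x (2 detector contrasts + 3 model terms)
        assert len(out) == 9 * 5
        assert set(out.columns) >= {"feature", "contrast", "test", "p_value", "significant"}
        assert (out["significant_bonferroni"] <= out["significant"]).all()

    def test_strong_effect_flagged(self, rng):
        out = feature_statistics(self._table(rng, effect=2.0), "tilting", boxcox="never")
        mw = out[(out.test == "mann-whitney-u") & (out.contrast == "condition[distal]")]
        assert mw["significant"].all()
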
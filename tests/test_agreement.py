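import numpy as np
import pandas as pd
import pytest
from scipy import stats

import frailtykit as fk
from frailtykit.agreement import (
    PairedMeasurements,
    adjusted_compare,
    bland_altman,
    cohens_d,
    correlation_label,
    effect_size_label,
    pearson,
)
from frailtykit.errors import ComputationError, ValidationError


def _pairs(a, b):
    a = np.asarray(a, dtype=float)
    return PairedMeasurements([f"s{i}" for i in range(a.size)], a, np.asarray(b, dtype=float))


class TestPearson:
    def test_perfect_affine_relation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, p, label = pearson(_pairs(x, 2 * x + 1))
        assert r == pytest.approx(1.0)
        assert label == "very strong"

    def test_perfect_negative(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, _, _ = pearson(_pairs(x, -x))
        assert r == pytest.approx(-1.0)

    def test_five_point_hand_formula(self):
        # oracle: expanded covariance formula on {(1,2),(2,1),(3,4),(4,3),(5,6)}
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        expected = sxy / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        r, p, _ = pearson(_pairs(x, y))
        assert r == pytest.approx(expected, rel=1e-12)
        # p from the t transform with n−2 df
        t = r * np.sqrt(3 / (1 - r**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=3), rel=1e-9)

    def test_zero_variance_error(self):
        with pytest.raises(ComputationError, match="zero variance"):
            pearson(_pairs([1, 1, 1], [1, 2, 3]))

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r1, _, _ = pearson(_pairs(x, y))
        r2, _, _ = pearson(_pairs(3 * x + 7, 0.5 * y - 2))
        assert r2 == pytest.approx(r1, rel=1e-12)

    @pytest.mark.parametrize(
        "r,label",
        [(0.99, "very strong"), (0.80, "very strong"), (0.74, "strong"),
         (0.60, "strong"), (0.45, "moderate"), (0.23, "weak"), (-0.85, "very strong")],
    )
    def test_band_labels(self, r, label):
        assert correlation_label(r) == label


class TestBlandAltman:
    def test_identical_series(self):
        rep = bland_altman(_pairs([1, 2, 3, 4], [1, 2, 3, 4]))
        assert rep.bias == 0.0
        assert rep.loa_lower == 0.0 == rep.loa_upper

    def test_unit_sd_differences_give_196_limits(self):
        # differences {−1, 0, +1}: bias 0, sample sd 1 → limits ±1.96
        rep = bland_altman(_pairs([0, 1, 2], [1, 1, 1]))
        assert rep.bias == pytest.approx(0.0)
        assert rep.sd_diff == pytest.approx(1.0)
        assert rep.loa_upper == pytest.approx(1.96)
        assert rep.loa_lower == pytest.approx(-1.96)

    def test_hand_computed_example(self):
        # differences {1,2,3,4}: bias 2.5, sd 1.29099, limits −0.0303 / 5.0303
        rep = bland_altman(_pairs([2, 4, 6, 8], [1, 2, 3, 4]))
        assert rep.bias == pytest.approx(2.5)
        assert rep.sd_diff == pytest.approx(1.290994, rel=1e-6)
        assert rep.loa_lower == pytest.approx(-0.030349, abs=1e-5)
        assert rep.loa_upper == pytest.approx(5.030349, abs=1e-5)

    def test_limits_symmetric_about_bias(self):
        rng = np.random.default_rng(1)
        rep = bland_altman(_pairs(rng.normal(10, 2, 30), rng.normal(10, 2, 30)))
        assert rep.loa_upper - rep.bias == pytest.approx(1.96 * rep.sd_diff, abs=1e-9)
        assert rep.bias - rep.loa_lower == pytest.approx(1.96 * rep.sd_diff, abs=1e-9)

    def test_limits_widen_with_noise(self):
        rng = np.random.default_rng(2)
        base = rng.normal(100, 10, 40)
        widths = []
        for sd in (0.5, 2.0, 8.0):
            noisy = base + rng.normal(0, sd, 40)
            rep = bland_altman(_pairs(base, noisy))
            widths.append(rep.loa_upper - rep.loa_lower)
        assert widths[0] < widths[1] < widths[2]


class TestCohensD:
    def test_identical_groups(self):
        d, label = cohens_d([1, 2, 3], [1, 2, 3])
        assert d == 0.0
        assert label == "none"

    def test_unit_separation_is_large(self):
        # means 0 and 1, both sample sds 1, equal n → d = 1 ("large")
        a = [-1.0, 0.0, 1.0]
        b = [0.0, 1.0, 2.0]
        d, label = cohens_d(a, b)
        assert d == pytest.approx(1.0)
        assert label == "large"

    @pytest.mark.parametrize(
        "d,label",
        [(0.1, "none"), (0.3, "small"), (0.6, "medium"), (1.0, "large"), (1.35, "very large")],
    )
    def test_magnitude_labels(self, d, label):
        assert effect_size_label(d) == label

    def test_symmetric_and_scale_invariant(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 2, 15)
        d1, _ = cohens_d(a, b)
        d2, _ = cohens_d(b, a)
        d3, _ = cohens_d(5 * a, 5 * b)
        assert d1 == pytest.approx(d2) == pytest.approx(d3)


class TestAdjustedCompare:
    def _cohort(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        group = np.array(["ctl"] * (n // 2) + ["pat"] * (n - n // 2))
        age = rng.uniform(25, 80, n)
        bmi = rng.uniform(20, 35, n)
        y = 1.0 * (group == "pat") + 0.02 * age - 0.01 * bmi + rng.normal(0, 0.3, n)
        return y, group, age, bmi

    def test_constant_covariates_reduce_to_plain_t_test(self):
        y, group, _, _ = self._cohort()
        res = adjusted_compare(y, group, np.full(12, 50.0), np.full(12, 25.0))
        t = stats.ttest_ind(y[group == "ctl"], y[group == "pat"])
        assert res.adjusted_p == pytest.approx(t.pvalue, rel=1e-9)

    def test_confounded_outcome_has_null_group_effect(self):
        # outcome is a pure function of age; groups split at the age median
        rng = np.random.default_rng(4)
        age = rng.uniform(20, 80, 40)
        y = 2.0 + 0.1 * age
        group = np.where(age > np.median(age), "old", "young")
        bmi = rng.uniform(20, 30, 40)
        res = adjusted_compare(y, group, age, bmi)
        assert abs(res.group_coefficient) < 1e-8

    def test_matches_normal_equations_oracle(self):
        y, group, age, bmi = self._cohort(n=12, seed=7)
        res = adjusted_compare(y, group, age, bmi)
        X = np.column_stack([np.ones(12), (group == group[-1]).astype(float), age, bmi])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.group_coefficient == pytest.approx(beta[1], abs=1e-8)

    def test_collinear_covariates_named(self):
        y, group, age, _ = self._cohort()
        with pytest.raises(ValidationError, match="bmi"):
            adjusted_compare(y, group, age, 2.0 * age)  # bmi ∝ age

    def test_effect_size_from_raw_groups(self):
        y, group, age, bmi = self._cohort(n=30, seed=9)
        res = adjusted_compare(y, group, age, bmi)
        d, label = cohens_d(y[group == "ctl"], y[group == "pat"])
        assert res.cohens_d == pytest.approx(d)
        assert res.d_label == label
        assert res.adjusted_d >= 0


class TestCompareFeatureTables:
    def _table(self, seed=0, jitter=0.0):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(11)]
        base = rng.normal(100, 20, 11)
        return pd.DataFrame(
            {"speed": base + jitter * rng.normal(size=11), "flexion_time": rng.uniform(0.2, 0.5, 11)},
            index=ids,
        )

    def test_identical_tables_have_zero_bias(self):
        df = self._table()
        rep = fk.compare_feature_tables(df, df.copy())
        assert (rep["bias"] == 0).all()
        assert rep["pearson_r"].to_numpy() == pytest.approx(1.0)

    def test_mismatched_subject_ids_error(self):
        df_a = self._table()
        df_b = self._table().rename(index={"s0": "s99"})
        with pytest.raises(ValidationError, match="s99"):
            fk.compare_feature_tables(df_a, df_b)
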
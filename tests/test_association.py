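import numpy as np
import pandas as pd
import pytest
from math import comb

from gpscore.data_model import NonConvergenceError, SingularDesignError
from gpscore.association import (
    DEFAULT_ADJUSTMENT,
    direction_consistency,
    direction_consistency_normal_approx,
    encode_covariates,
    explained_variance_decomposition,
    fit_linear,
    fit_logistic,
    quartile_or_analysis,
)


def random_covariates(n, rng):
    return pd.DataFrame({
        "age": rng.uniform(30, 64, n),
        "sex": rng.choice(["male", "female"], n),
        "smoking": rng.choice(["never", "current", "former"], n),
        "activity": rng.choice(["none", "low", "medium", "high"], n),
    }, index=[f"I{i}" for i in range(n)])


class TestLinear:
    def test_perfect_fit_recovers_slope_and_full_r2(self):
        x = pd.Series(np.arange(50.0))
        y = 2.0 * x
        res = fit_linear(y, x)
        assert res.estimate == pytest.approx(2.0, abs=1e-10)
        assert res.r2_percent == pytest.approx(100.0, abs=1e-8)

    def test_matches_closed_form_simple_regression(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(size=300))
        y = pd.Series(0.7 * x + rng.normal(size=300))
        res = fit_linear(y, x)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert res.estimate == pytest.approx(slope, abs=1e-10)
        assert res.lcl < res.estimate < res.ucl
        assert res.ucl - res.estimate == pytest.approx(1.959964 * res.se, rel=1e-4)

    def test_type_one_error_is_nominal(self):
        """Null exposure: rejection rate at alpha=0.05 stays in [3.5%, 6.5%]."""
        rng = np.random.default_rng(123)
        n, reps = 500, 1000
        rejections = 0
        for _ in range(reps):
            x = pd.Series(rng.normal(size=n))
            y = pd.Series(rng.normal(size=n))
            rejections += fit_linear(y, x).p <= 0.05
        assert 0.035 <= rejections / reps <= 0.065

    def test_adjustment_changes_nothing_for_independent_covariates(self):
        rng = np.random.default_rng(5)
        n = 4000
        cov = random_covariates(n, rng)
        x = pd.Series(rng.normal(size=n), index=cov.index)
        y = pd.Series(0.5 * x + rng.normal(size=n), index=cov.index)
        crude = fit_linear(y, x)
        adjusted = fit_linear(y, x, cov, DEFAULT_ADJUSTMENT)
        assert adjusted.estimate == pytest.approx(crude.estimate, abs=3 * crude.se / np.sqrt(1))

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(1)
        n = 100
        cov = random_covariates(n, rng)
        cov["bmi"] = cov["age"] * 2.0  # exact collinearity with age
        x = pd.Series(rng.normal(size=n), index=cov.index)
        y = pd.Series(rng.normal(size=n), index=cov.index)
        with pytest.raises(SingularDesignError, match="age|bmi"):
            fit_linear(y, x, cov, ("age", "bmi"))

    def test_listwise_deletion(self):
        x = pd.Series([1.0, 2.0, 3.0, np.nan, 5.0] * 10)
        y = pd.Series([2.0, 4.1, 5.9, 8.0, np.nan] * 10)
        res = fit_linear(y, x)
        assert res.n == 30


class TestLogistic:
    def test_crude_or_matches_hand_cross_product(self):
        """Collapsed 2x2 from the printed quartile table: 52/71 vs 33/91."""
        exposure = pd.Series([1.0] * (52 + 71) + [0.0] * (33 + 91))
        case = pd.Series([1.0] * 52 + [0.0] * 71 + [1.0] * 33 + [0.0] * 91)
        res = fit_logistic(case, exposure)
        assert res.or_value == pytest.approx((52 * 91) / (33 * 71), abs=1e-6)
        assert res.or_value == pytest.approx(2.02, abs=0.005)

    def test_random_2x2_tables_match_cross_product(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a, b, c, d = rng.integers(5, 80, size=4)
            exposure = pd.Series([1.0] * (a + b) + [0.0] * (c + d))
            case = pd.Series([1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d)
            res = fit_logistic(case, exposure)
            assert res.or_value == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_null_exposure_gives_or_near_one(self):
        rng = np.random.default_rng(3)
        n = 5000
        x = pd.Series(rng.normal(size=n))
        y = pd.Series(rng.integers(0, 2, size=n).astype(float))
        res = fit_logistic(y, x)
        assert res.or_value == pytest.approx(1.0, abs=0.05)
        assert res.lcl < res.estimate < res.ucl

    def test_separation_raises_nonconvergence(self):
        x = pd.Series(np.r_[np.zeros(20), np.ones(20)])
        y = pd.Series(np.r_[np.zeros(20), np.ones(20)])
        with pytest.raises(NonConvergenceError):
            fit_logistic(y, x)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.Series([1.0] * 10), pd.Series(np.arange(10.0)))


class TestQuartileTable:
    def test_reference_row_is_exactly_one(self):
        rng = np.random.default_rng(21)
        n = 800
        gps = pd.Series(rng.normal(26, 3.5, n), index=[f"I{i}" for i in range(n)])
        case = pd.Series(rng.integers(0, 2, n).astype(float), index=gps.index)
        table = quartile_or_analysis(gps, case, adjustment_set=())
        assert table.rows[0].or_value == 1.0
        assert sum(r.n_cases + r.n_controls for r in table.rows) == n

    def test_monotone_risk_gives_increasing_ors_and_small_trend_p(self):
        rng = np.random.default_rng(17)
        n = 2000
        cov = random_covariates(n, rng)
        gps = pd.Series(rng.normal(26, 3.5, n), index=cov.index)
        logit = -1.5 + 0.25 * (gps - gps.mean())
        case = pd.Series((rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float),
                         index=cov.index)
        table = quartile_or_analysis(gps, case, cov, DEFAULT_ADJUSTMENT)
        ors = [r.or_value for r in table.rows]
        assert all(b >= a * 0.9 for a, b in zip(ors, ors[1:]))  # non-decreasing (noise slack)
        assert table.p_trend < 0.01

    def test_null_trend_p_is_uniform(self):
        rng = np.random.default_rng(33)
        n, reps = 400, 300
        ps = []
        for _ in range(reps):
            gps = pd.Series(rng.normal(26, 3.5, n))
            case = pd.Series(rng.integers(0, 2, n).astype(float))
            ps.append(quartile_or_analysis(gps, case, adjustment_set=()).p_trend)
        rate = np.mean(np.array(ps) <= 0.05)
        assert 0.02 <= rate <= 0.09

    def test_empty_cell_flagged_trend_still_computed(self):
        # top quartile has no controls at all; the other quartiles are mixed
        rng = np.random.default_rng(6)
        gps = pd.Series(np.arange(100.0))
        case = pd.Series(rng.integers(0, 2, 100).astype(float))
        case.iloc[75:] = 1.0
        table = quartile_or_analysis(gps, case, adjustment_set=())
        assert table.rows[3].or_value is None
        assert table.rows[1].or_value is not None
        assert np.isfinite(table.p_trend)


class TestVarianceDecomposition:
    def test_outcome_equal_to_score(self):
        rng = np.random.default_rng(2)
        n = 500
        cov = random_covariates(n, rng)
        gps = pd.Series(rng.normal(26, 3.5, n), index=cov.index)
        r2c, r2f, r2cov = explained_variance_decomposition(gps, gps, cov)
        assert r2c == pytest.approx(100.0, abs=1e-6)
        assert r2f == pytest.approx(100.0, abs=1e-6)
        assert r2cov == pytest.approx(0.0, abs=1e-6)

    def test_independent_outcome_near_zero(self):
        rng = np.random.default_rng(4)
        n = 2000
        cov = random_covariates(n, rng)
        gps = pd.Series(rng.normal(26, 3.5, n), index=cov.index)
        y = pd.Series(rng.normal(size=n), index=cov.index)
        r2c, r2f, r2cov = explained_variance_decomposition(y, gps, cov)
        assert r2c < 0.5
        assert r2f < 1.0


class TestDirectionConsistency:
    def test_exact_tail_matches_brute_force(self):
        betas = np.r_[np.ones(23), -np.ones(6)]
        k, n, p = direction_consistency(betas)
        assert (k, n) == (23, 29)
        brute = sum(comb(29, j) for j in range(23, 30)) / 2**29
        assert p == pytest.approx(brute, rel=1e-12)
        assert round(p, 5) == 0.00116

    def test_all_consistent_is_two_to_minus_n(self):
        k, n, p = direction_consistency(np.ones(12))
        assert p == pytest.approx(2.0**-12, rel=1e-12)

    def test_half_consistent_is_not_significant(self):
        betas = np.r_[np.ones(15), -np.ones(14)]
        _, _, p = direction_consistency(betas)
        assert p > 0.4

    def test_zero_beta_counts_as_inconsistent(self):
        k, _, _ = direction_consistency(np.array([0.0, 1.0, -1.0]))
        assert k == 1

    def test_normal_approximation_close_to_exact(self):
        p_norm = direction_consistency_normal_approx(23, 29)
        assert p_norm == pytest.approx(0.0008, abs=2e-4)


class TestEncoding:
    def test_reference_levels(self):
        cov = pd.DataFrame({
            "age": [40, 50], "sex": ["male", "female"],
            "smoking": ["never", "current"], "activity": ["none", "high"],
        }, index=["a", "b"])
        enc = encode_covariates(cov, DEFAULT_ADJUSTMENT)
        assert enc.loc["a"].tolist() == [40.0, 0.0, 0.0, 0.0]
        assert enc.loc["b"].tolist() == [50.0, 1.0, 3.0, 1.0]

    def test_three_level_smoking_coding(self):
        cov = pd.DataFrame({"smoking": ["never", "current", "former"]},
                           index=["a", "b", "c"])
        enc = encode_covariates(cov, ("smoking",), smoking_coding="levels")
        assert list(enc.columns) == ["current_smoker", "former_smoker"]
        assert enc.sum().tolist() == [1.0, 1.0]
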
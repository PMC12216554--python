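"""MR estimators: arithmetic identities, oracle equivalence, robustness."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from mrscreen.estimators import (
    fit_all,
    ivw,
    mode_estimator,
    mr_egger,
    run_all_methods,
    wald_ratio,
    weighted_median,
)
from mrscreen.exceptions import DomainError, InsufficientInstruments
from mrscreen.gwas_io import harmonized_from_arrays
from mrscreen.simulate import SimulationConfig, simulate_effect_arrays


def _fixture_arrays(k=20, seed=42, theta=0.25):
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.05, 0.2, k) * rng.choice([-1, 1], k)
    se_bx = np.full(k, 0.01)
    se_by = rng.uniform(0.005, 0.02, k)
    by = theta * bx + rng.normal(0, se_by)
    return bx, se_bx, by, se_by


class TestWaldRatio:
    def test_zero_numerator(self):
        assert wald_ratio(0.2, 0.0, 0.01).beta == 0.0

    def test_unit_denominator_identity(self):
        est = wald_ratio(1.0, 0.3, 0.05)
        assert est.beta == 0.3
        assert est.se == 0.05

    def test_hand_arithmetic(self):
        est = wald_ratio(0.2, 0.05, 0.01)
        assert est.beta == pytest.approx(0.25)
        assert est.se == pytest.approx(0.05)

    def test_zero_denominator_errors(self):
        with pytest.raises(DomainError):
            wald_ratio(0.0, 0.1, 0.01)


class TestIVW:
    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstruments):
            ivw([0.1], [0.2], [0.01])

    def test_reduces_to_wald_when_one_weight_dominates(self):
        # second variant contributes ~zero weight
        est = ivw([0.2, 0.1], [0.05, 0.0], [0.01, 1e6], "fixed")
        wald = wald_ratio(0.2, 0.05, 0.01)
        assert est.beta == pytest.approx(wald.beta, rel=1e-9)
        assert est.se == pytest.approx(wald.se, rel=1e-9)

    def test_homogeneous_case(self):
        bx = np.array([0.1, 0.2, 0.15])
        by = 0.5 * bx
        se = np.full(3, 0.01)
        fixed = ivw(bx, by, se, "fixed")
        random = ivw(bx, by, se)
        assert fixed.beta == pytest.approx(0.5)
        assert fixed.extras["q_stat"] == pytest.approx(0.0, abs=1e-20)
        assert random.se == fixed.se  # no over-dispersion to inflate

    def test_matches_wls_through_origin_oracle(self):
        bx, _, by, se_by = _fixture_arrays()
        fit = sm.WLS(by, bx, weights=1.0 / se_by**2).fit()
        est = ivw(bx, by, se_by, "fixed")
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels scales the covariance by the residual variance;
        # undo that to compare with the fixed-effects SE
        se_unscaled = fit.bse[0] / np.sqrt(fit.scale)
        assert est.se == pytest.approx(se_unscaled, abs=1e-10)


class TestEgger:
    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstruments):
            mr_egger([0.1, 0.2], [0.1, 0.1], [0.01, 0.01])

    def test_matches_wls_oracle(self):
        bx, _, by, se_by = _fixture_arrays()
        sign = np.sign(bx)
        bxo, byo = bx * sign, by * sign
        X = sm.add_constant(bxo)
        fit = sm.WLS(byo, X, weights=1.0 / se_by**2).fit()
        est = mr_egger(bx, by, se_by)
        assert est.extras["intercept"] == pytest.approx(fit.params[0], abs=1e-10)
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)

    def test_constant_shift_moves_intercept_not_slope(self):
        bx = np.array([0.1, 0.15, 0.2, 0.25])
        by = 0.4 * bx
        se = np.full(4, 0.01)
        base = mr_egger(bx, by, se)
        shifted = mr_egger(bx, by + 0.03, se)
        assert shifted.extras["intercept"] - base.extras["intercept"] == pytest.approx(0.03)
        assert shifted.beta == pytest.approx(base.beta, abs=1e-12)

    def test_null_intercept_rejection_near_nominal(self):
        """No systematic pleiotropy detection under the null."""
        cfg = SimulationConfig(n_snps_causal=30, theta_direct=0.2, n_exposure=100_000)
        rng = np.random.default_rng(99)
        rej = 0
        reps = 400
        for _ in range(reps):
            a = simulate_effect_arrays(cfg, rng)
            rej += mr_egger(a["bx"], a["by"], a["se_y"]).extras["intercept_p"] < 0.05
        # 99% binomial envelope around 0.05 for 400 draws
        assert rej / reps < 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / reps)


class TestWeightedMedian:
    def test_median_robust_to_one_outlier(self):
        bx = np.ones(3)
        by = np.array([1.0, 2.0, 100.0])
        se = np.ones(3)
        est = weighted_median(bx, by, se, n_boot=100, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_all_equal_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        by = 3.0 * bx
        se = np.array([0.01, 0.01, 0.01])
        est = weighted_median(bx, by, se, n_boot=200, seed=2)
        assert est.beta == pytest.approx(3.0)
        assert est.se < 0.5

    def test_consistent_under_minority_pleiotropy_where_ivw_biased(self):
        """With 40% invalid instruments the median tracks the truth, IVW does not."""
        cfg = SimulationConfig(
            n_snps_causal=10, theta_direct=0.3, pleiotropy_mode="correlated",
            pleiotropy_frac=0.4, pleiotropy_rho=0.5, pleiotropy_sd=0.0,
            gamma_dist="very_strong", n_exposure=100_000,
        )
        rng = np.random.default_rng(5)
        wm, iv = [], []
        for i in range(200):
            a = simulate_effect_arrays(cfg, rng)
            wm.append(
                weighted_median(a["bx"], a["by"], a["se_y"], a["se_x"],
                                n_boot=100, seed=i).beta
            )
            iv.append(ivw(a["bx"], a["by"], a["se_y"]).beta)
        wm, iv = np.array(wm), np.array(iv)
        assert abs(wm.mean() - 0.3) < 3 * wm.std(ddof=1)
        assert abs(iv.mean() - 0.3) > 3 * iv.std(ddof=1)


class TestModeEstimators:
    def test_majority_cluster(self):
        bx = np.ones(4)
        by = np.array([1.0, 1.0, 1.0, 5.0])
        se = np.ones(4)
        est = mode_estimator(bx, by, se, weighted=False, n_boot=100, seed=3)
        assert est.beta == pytest.approx(1.0, abs=0.1)

    def test_symmetric_ratios_give_centre(self):
        bx = np.ones(5)
        by = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        se = np.ones(5)
        est = mode_estimator(bx, by, se, weighted=False, n_boot=100, seed=4)
        assert est.beta == pytest.approx(2.0, abs=1e-6)

    def test_bootstrap_se_stable_across_seeds(self):
        bx, se_bx, by, se_by = _fixture_arrays(k=15, seed=7)
        a = mode_estimator(bx, by, se_by, se_bx, n_boot=2000, seed=11)
        b = mode_estimator(bx, by, se_by, se_bx, n_boot=2000, seed=12)
        assert abs(a.se - b.se) / a.se < 0.10


class TestRunAllMethods:
    def test_single_snp_gives_wald_only(self):
        hset = harmonized_from_arrays([0.2], [0.01], [0.05], [0.02])
        table = run_all_methods(hset, seed=1)
        assert table["method"].tolist() == ["wald_ratio"]

    def test_many_snps_exclude_wald(self):
        bx, se_bx, by, se_by = _fixture_arrays(k=10)
        hset = harmonized_from_arrays(bx, se_bx, by, se_by)
        table = run_all_methods(hset, seed=1, n_boot=100)
        assert "wald_ratio" not in set(table["method"])
        assert {
            "ivw_fixed", "ivw_random", "egger", "weighted_median",
            "simple_mode", "weighted_mode",
        } == set(table["method"])

    def test_or_scale_matches_exp_beta(self):
        hset = harmonized_from_arrays([1.0], [0.01], [0.14201], [0.04], binary_outcome=True)
        table = run_all_methods(hset, seed=1)
        assert table.loc[0, "or"] == pytest.approx(1.1526, abs=5e-5)


class TestEquivariance:
    @pytest.mark.parametrize("method", ["ivw", "egger", "weighted_median", "mode"])
    def test_negating_outcome_negates_estimate(self, method):
        bx, se_bx, by, se_by = _fixture_arrays(k=12, seed=21)
        def fit(yy):
            if method == "ivw":
                return ivw(bx, yy, se_by).beta
            if method == "egger":
                return mr_egger(bx, yy, se_by).beta
            if method == "weighted_median":
                return weighted_median(bx, yy, se_by, n_boot=100, seed=5).beta
            return mode_estimator(bx, yy, se_by, n_boot=100, seed=5).beta
        assert fit(-by) == pytest.approx(-fit(by), rel=1e-9, abs=1e-12)

    @given(c=st.floats(0.1, 10.0))
    def test_scaling_exposure_scales_estimate_inversely(self, c):
        bx, se_bx, by, se_by = _fixture_arrays(k=8, seed=33)
        base = ivw(bx, by, se_by).beta
        scaled = ivw(c * bx, by, se_by).beta
        assert scaled == pytest.approx(base / c, rel=1e-9)


class TestCalibration:
    def test_ivw_type_one_error_under_null(self):
        """Fixed-effects IVW rejects at ~5% under the simulated global null."""
        cfg = SimulationConfig(n_snps_causal=50)
        rng = np.random.default_rng(77)
        reps = 600
        rej = 0
        for _ in range(reps):
            a = simulate_effect_arrays(cfg, rng)
            rej += ivw(a["bx"], a["by"], a["se_y"], "fixed").pvalue < 0.05
        rate = rej / reps
        half = 2.58 * np.sqrt(0.05 * 0.95 / reps)  # 99% envelope
        assert 0.05 - half < rate < 0.05 + half

    def test_ivw_parameter_recovery(self):
        """Mean IVW estimate tracks the true effect with strong instruments."""
        cfg = SimulationConfig(
            n_snps_causal=50, theta_direct=0.3, gamma_dist="very_strong",
            n_exposure=100_000,
        )
        rng = np.random.default_rng(88)
        betas = np.array(
            [ivw(*(lambda a: (a["bx"], a["by"], a["se_y"]))(
                simulate_effect_arrays(cfg, rng))).beta for _ in range(300)]
        )
        mcse = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean() - 0.3) < 3 * mcse
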
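"""Sequential estimator menu: MLE variants, conditional and penalized MLE."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from gsmediate import (
    MediationParams,
    SequentialSufficientStats,
    conditional_mle,
    fit_total_model,
    mle_estimates,
    penalized_mle,
    secondary_correlation,
    simulate_trial_data,
)
from gsmediate.regression import FitResult

B1 = 2.1783


def theta_stats(z1, i1, i2, est, rho=1.0):
    return SequentialSufficientStats(
        z1=z1, info1=i1, info2=i2, estimate_obs=est,
        se_obs=1.0 / math.sqrt(i2), rho=rho,
    )


class TestMLEVariants:
    def test_noise_free_all_variants_recover_truth(self, rng):
        p = MediationParams(a=0.5, b=0.4, c_prime=0.2, sigma_m=1.0, sigma_y=1e-10)
        df = simulate_trial_data(p, 200, 100, rng)
        for stop_stage in (1, 2):
            est = mle_estimates(df, stop_stage)
            for label in est.labels():
                assert est.get(label, "b") == pytest.approx(0.4, abs=1e-6)
                assert est.get(label, "c_prime") == pytest.approx(0.2, abs=1e-6)

    def test_pooled_theta_is_precision_weighted_combination(self, rng):
        p = MediationParams(a=0.39, b=0.14, c_prime=0.39)
        df = simulate_trial_data(p, 191, 96, rng)
        est = mle_estimates(df, 2)
        th1 = fit_total_model(df[df.stage == 1]).estimate("theta")
        th2 = fit_total_model(df[df.stage == 2]).estimate("theta")
        pooled = (96 * th1 + 95 * th2) / 191
        assert est.get("mle_all", "theta") == pytest.approx(pooled, abs=1e-10)

    def test_branch_population_contract(self, rng):
        df = simulate_trial_data(MediationParams(0.2, 0.2, 0.2), 100, 40, rng)
        assert mle_estimates(df, 1).labels() == ("mle_1",)
        assert set(mle_estimates(df, 2).labels()) == {"mle_all", "mle_2"}

    def test_invalid_stage_rejected(self, rng):
        df = simulate_trial_data(MediationParams(0.2, 0.2, 0.2), 100, 40, rng)
        with pytest.raises(ValueError):
            mle_estimates(df, 3)


class TestConditionalMLE:
    def test_grid_search_oracle(self):
        # independently coded conditional log-likelihood, brute-forced
        z1, i1, i2, theta_all = 1.0, 50.0, 100.0, 0.25
        s1, s2 = z1 * math.sqrt(i1), theta_all * i2
        grid = np.arange(-1.0, 1.0, 1e-5)
        ll = (
            norm.logpdf(s1, grid * i1, math.sqrt(i1))
            + norm.logpdf(s2 - s1, grid * (i2 - i1), math.sqrt(i2 - i1))
            - np.log(
                norm.cdf(B1 - grid * math.sqrt(i1))
                - norm.cdf(-B1 - grid * math.sqrt(i1))
            )
        )
        oracle = grid[np.argmax(ll)]
        est, ok = conditional_mle(theta_stats(z1, i1, i2, theta_all), B1)
        assert ok
        assert est == pytest.approx(oracle, abs=1e-4)

    def test_sure_conditioning_event_recovers_mle(self):
        est, ok = conditional_mle(theta_stats(1.0, 50.0, 100.0, 0.25), 60.0)
        assert ok
        assert est == pytest.approx(0.25, abs=1e-6)

    def test_requires_continuation(self):
        with pytest.raises(ValueError):
            conditional_mle(theta_stats(3.0, 50.0, 100.0, 0.4), B1)

    def test_corrects_upwards_after_continuation(self):
        # continuation selects low stage-1 statistics, so the pooled MLE
        # underestimates theta and the conditional MLE corrects upwards
        est, ok = conditional_mle(theta_stats(2.0, 50.0, 100.0, 0.25), B1)
        assert ok and est > 0.25


class TestPenalizedMLE:
    @staticmethod
    def oracle_pmle(z1, i1, b1):
        """Brute-force penalized truncated likelihood, numerical information."""
        sqrt_i1 = math.sqrt(i1)

        def lc(t):
            m = t * sqrt_i1
            p_stop = norm.sf(b1 - m) + norm.cdf(-b1 - m)
            return norm.logpdf(z1 - m) - np.log(p_stop)

        grid = np.arange(-1.0, 1.5, 1e-5)
        h = 1e-4
        info = -(lc(grid + h) - 2 * lc(grid) + lc(grid - h)) / h**2
        obj = np.where(info > 0, lc(grid) + 0.5 * np.log(np.abs(info)), -np.inf)
        return grid[np.argmax(obj)]

    def test_grid_search_oracle(self):
        z1, i1 = 2.5, 50.0
        stats = SequentialSufficientStats(
            z1=z1, info1=i1, info2=2 * i1,
            estimate_obs=z1 / math.sqrt(i1), se_obs=1 / math.sqrt(i1),
        )
        est, ok = penalized_mle(stats, B1)
        assert ok
        assert est == pytest.approx(self.oracle_pmle(z1, i1, B1), abs=1e-4)

    def test_truncation_correction_vanishes_far_from_boundary(self):
        i1 = 50.0
        z1 = B1 + 5.0
        se = 1 / math.sqrt(i1)
        stats = SequentialSufficientStats(
            z1=z1, info1=i1, info2=2 * i1, estimate_obs=z1 * se, se_obs=se
        )
        est, ok = penalized_mle(stats, B1)
        assert ok
        assert abs(est - z1 * se) < 0.02 * se

    def test_requires_early_stop(self):
        stats = SequentialSufficientStats(
            z1=1.0, info1=50.0, info2=100.0, estimate_obs=0.1, se_obs=0.1
        )
        with pytest.raises(ValueError):
            penalized_mle(stats, B1)

    def test_reduces_estimate_just_above_boundary(self):
        # immediately past the boundary the truncated likelihood pulls the
        # stage-one MLE towards zero
        i1 = 50.0
        z1 = B1 + 0.05
        se = 1 / math.sqrt(i1)
        stats = SequentialSufficientStats(
            z1=z1, info1=i1, info2=2 * i1, estimate_obs=z1 * se, se_obs=se
        )
        est, ok = penalized_mle(stats, B1)
        assert ok and est < z1 * se


def _fake_fits(b_hat, sm2, sy2, a_hat=0.3, se_theta=0.1, var_c=0.008, cov_cb=-0.001):
    mk = lambda names, params, cov, rv: FitResult(
        names=names, params=np.asarray(params, float),
        bse=np.sqrt(np.diag(cov)), tvalues=np.zeros(len(names)),
        pvalues=np.ones(len(names)), df_resid=100, resid_var=rv,
        nobs=103, cov_params=np.asarray(cov, float),
    )
    total = mk(("intercept", "theta"), [0.0, 0.2],
               [[1e-4, 0], [0, se_theta**2]], sm2 * b_hat**2 + sy2)
    mediator = mk(("intercept", "a"), [0.0, a_hat],
                  [[1e-4, 0], [0, 0.01]], sm2)
    outcome = mk(
        ("intercept", "c_prime", "b"), [0.0, 0.1, b_hat],
        [[1e-4, 0, 0], [0, var_c, cov_cb], [0, cov_cb, 0.004]], sy2,
    )
    return {"total": total, "mediator": mediator, "outcome": outcome}


class TestSecondaryCorrelation:
    def test_zero_mediator_outcome_path_decouples_a(self):
        fits = _fake_fits(b_hat=0.0, sm2=1.0, sy2=1.0)
        assert secondary_correlation(fits, "a") == 0.0

    def test_formula_for_a(self):
        fits = _fake_fits(b_hat=0.59, sm2=1.0, sy2=1.0)
        assert secondary_correlation(fits, "a") == pytest.approx(
            0.59 / math.sqrt(1.3481), abs=1e-12
        )

    def test_monte_carlo_correlation_oracle(self):
        # empirical corr(theta_hat, a_hat) across replicates matches
        # b*sigma_m/sqrt(b^2 sigma_m^2 + sigma_y^2)
        rng = np.random.default_rng(123)
        n, reps, b = 500, 10_000, 0.59
        em0 = rng.standard_normal((reps, n))
        em1 = rng.standard_normal((reps, n))
        ey0 = rng.standard_normal((reps, n))
        ey1 = rng.standard_normal((reps, n))
        a_hat = em1.mean(1) - em0.mean(1)  # a = 0 wlog
        theta_hat = (b * em1 + ey1).mean(1) - (b * em0 + ey0).mean(1)
        emp = np.corrcoef(theta_hat, a_hat)[0, 1]
        assert emp == pytest.approx(b / math.sqrt(b**2 + 1), abs=0.02)

    def test_clamped_inside_unit_interval(self):
        fits = _fake_fits(b_hat=50.0, sm2=1.0, sy2=1e-6)
        assert abs(secondary_correlation(fits, "a")) <= 0.999
        fits = _fake_fits(b_hat=0.5, sm2=1.0, sy2=1.0,
                          se_theta=0.0892, var_c=0.0079, cov_cb=0.0)
        assert abs(secondary_correlation(fits, "c_prime")) <= 0.999

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            secondary_correlation(_fake_fits(0.2, 1, 1), "b")

    def test_degenerate_variances_signal(self):
        fits = _fake_fits(b_hat=0.2, sm2=0.0, sy2=1.0)
        with pytest.raises(ValueError):
            secondary_correlation(fits, "a")


class TestSecondaryAdjustment:
    def test_secondary_cmle_correction_scales_with_theta_shift(self):
        # the secondary correction equals rho*(se_b/se_t)*(theta_hat - theta~)
        # with theta~ the primary conditional MLE
        base = dict(z1=2.0, info1=50.0, info2=100.0, theta_obs=0.25, se_theta=0.1)
        theta_tilde, ok = conditional_mle(
            SequentialSufficientStats(estimate_obs=0.25, se_obs=0.1, rho=1.0, **base),
            B1,
        )
        assert ok and theta_tilde > 0.25  # continuation corrects theta upwards
        est, ok = conditional_mle(
            SequentialSufficientStats(estimate_obs=0.3, se_obs=0.08, rho=0.5, **base),
            B1,
        )
        assert ok
        expected = 0.3 - 0.5 * (0.08 / 0.1) * (0.25 - theta_tilde)
        assert est == pytest.approx(expected, abs=1e-8)
        assert est > 0.3  # positively correlated secondary shifts up too

    def test_secondary_pmle_corrects_towards_null(self):
        stats = SequentialSufficientStats(
            z1=2.4, info1=50.0, info2=100.0, estimate_obs=0.35, se_obs=0.1,
            rho=0.5, theta_obs=2.4 / np.sqrt(50.0), se_theta=1 / np.sqrt(50.0),
        )
        est, ok = penalized_mle(stats, B1)
        assert ok and est < 0.35

    def test_zero_correlation_leaves_secondary_untouched(self):
        stats = SequentialSufficientStats(
            z1=2.4, info1=50.0, info2=100.0, estimate_obs=0.35, se_obs=0.1,
            rho=0.0, theta_obs=2.4 / np.sqrt(50.0), se_theta=1 / np.sqrt(50.0),
        )
        est, ok = penalized_mle(stats, B1)
        assert ok and est == pytest.approx(0.35, abs=1e-12)

    def test_secondary_stats_require_theta_estimate(self):
        with pytest.raises(ValueError, match="theta_obs"):
            SequentialSufficientStats(
                z1=2.4, info1=50.0, info2=100.0, estimate_obs=0.35, se_obs=0.1,
                rho=0.5,
            )
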
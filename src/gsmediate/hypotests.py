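"""Hypothesis tests for the three mediation null hypotheses.

H01: theta = 0 (total effect) is tested against the group-sequential
boundaries and lives in the trial engine; this module provides the secondary
tests run at the 5% level regardless of stopping stage:

* H02: c' = 0 -- two-sided t-test on the outcome-model coefficient;
* H03: a b = 0 -- four procedures: first/second-order Sobel (delta-method)
  tests, the joint significance test, and the Monte-Carlo confidence-interval
  test that simulates the sampling distribution of ``a_hat * b_hat``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .regression import FitResult

__all__ = [
    "TestResult",
    "sobel_test",
    "joint_significance_test",
    "monte_carlo_ci_test",
    "direct_effect_test",
]


@dataclass(frozen=True)
class TestResult:
    hypothesis: str  # H01 | H02 | H03
    method: str  # gsd-boundary | t-test | sobel1 | sobel2 | joint | mc-ci
    reject: bool
    statistic: float | None = None
    p_value: float | None = None
    interval: tuple[float, float] | None = None
    stage: int | None = None


def sobel_test(
    a_hat: float,
    se_a: float,
    b_hat: float,
    se_b: float,
    order: int = 1,
    alpha: float = 0.05,
) -> TestResult:
    """Delta-method (Sobel) Wald test of the indirect effect ``a b``.

    First order:  SE^2 = b^2 se_a^2 + a^2 se_b^2.
    Second order: adds the ``se_a^2 se_b^2`` term, so the second-order test
    is never more significant than the first-order one.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if not (se_a > 0 and se_b > 0):
        if a_hat * b_hat == 0.0:
            return TestResult("H03", f"sobel{order}", False, 0.0, 1.0)
        raise ValueError("zero standard errors with a nonzero indirect estimate")
    var = b_hat**2 * se_a**2 + a_hat**2 * se_b**2
    if order == 2:
        var += se_a**2 * se_b**2
    se = np.sqrt(var)
    if se == 0.0:
        return TestResult("H03", f"sobel{order}", False, 0.0, 1.0)
    z = a_hat * b_hat / se
    p = 2.0 * norm.sf(abs(z))
    return TestResult(
        "H03",
        f"sobel{order}",
        reject=bool(abs(z) > norm.ppf(1.0 - alpha / 2.0)),
        statistic=float(z),
        p_value=float(p),
    )


def joint_significance_test(p_a: float, p_b: float, alpha: float = 0.05) -> TestResult:
    """Reject ``a b = 0`` iff both path p-values fall below alpha."""
    for p in (p_a, p_b):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    return TestResult(
        "H03",
        "joint",
        reject=bool(p_a < alpha and p_b < alpha),
        p_value=float(max(p_a, p_b)),
    )


def monte_carlo_ci_test(
    a_hat: float,
    se_a: float,
    b_hat: float,
    se_b: float,
    alpha: float = 0.05,
    n_draws: int = 20_000,
    rng: np.random.Generator | None = None,
) -> TestResult:
    """Percentile interval for ``a b`` from simulated coefficient draws.

    Draws ``a* ~ N(a_hat, se_a^2)`` and ``b* ~ N(b_hat, se_b^2)``
    independently and takes the empirical (alpha/2, 1-alpha/2) percentiles of
    ``a* b*`` (linear interpolation); rejects iff 0 lies outside.
    """
    if n_draws < 1000:
        raise ValueError("n_draws below the 1000-draw floor")
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be nonnegative")
    if rng is None:
        rng = np.random.default_rng()
    a_star = a_hat + se_a * rng.standard_normal(n_draws)
    b_star = b_hat + se_b * rng.standard_normal(n_draws)
    prod = a_star * b_star
    lo, hi = np.quantile(prod, [alpha / 2.0, 1.0 - alpha / 2.0])
    return TestResult(
        "H03",
        "mc-ci",
        reject=bool(lo > 0.0 or hi < 0.0),
        interval=(float(lo), float(hi)),
    )


def direct_effect_test(fit: FitResult, alpha: float = 0.05) -> TestResult:
    """Two-sided t-test of the direct effect c' from the outcome-model fit."""
    row = fit["c_prime"]
    return TestResult(
        "H02",
        "t-test",
        reject=bool(row["p"] < alpha),
        statistic=row["t"],
        p_value=row["p"],
    )
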
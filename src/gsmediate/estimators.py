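"""Estimators of the mediation parameters after a group-sequential trial.

Five estimators are reported, split by stopping stage:

* stopped at the interim: ``mle_1`` (stage-one OLS) and ``pmle`` (penalized
  MLE maximizing the Firth-penalized stage-one likelihood truncated to the
  stopping event);
* continued to the maximum sample size: ``mle_all`` (pooled OLS), ``mle_2``
  (stage-two records only) and ``cmle`` (MLE conditional on the continuation
  event ``|Z1| < b``).

Stopping is always driven by the stage-one statistic for the total effect
theta.  For theta itself the conditional (or penalized truncated) likelihood
of the score-scale statistics is maximized directly.  For the secondary
parameters ``a`` and ``c'`` the conditioning is carried through the joint
normal of the theta statistics and the target estimate with plug-in
correlation rho.  Profiling the target parameter out of that joint
conditional likelihood gives the exact closed form

    beta~ = beta_hat - rho * (se_beta / se_theta) * (theta_hat - theta~),

where ``(theta_hat, se_theta)`` are the theta MLE and its SE at the analysis
stage and ``theta~`` is the branch-appropriate adjusted theta (conditional
MLE after continuation, penalized MLE after stopping): given the theta MLE,
the stage-one statistic carries no extra information about the target, so
the secondary correction is the estimated selection bias of theta scaled by
the estimators' covariance.  The mediator-outcome path ``b`` is exempt from
adjustment: its OLS estimator is unaffected by stopping because the
intervention does not modify the mediator-outcome relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr

from . import regression

_SQRT_2PI = math.sqrt(2.0 * math.pi)


def _phi(x: float) -> float:
    return math.exp(-0.5 * x * x) / _SQRT_2PI


def _logaddexp(a: float, b: float) -> float:
    if a < b:
        a, b = b, a
    return a + math.log1p(math.exp(b - a))

__all__ = [
    "EstimateSet",
    "SequentialSufficientStats",
    "mle_estimates",
    "conditional_mle",
    "penalized_mle",
    "secondary_correlation",
]

PARAMS = ("theta", "a", "b", "c_prime")

#: which regression each parameter is read from
_PARAM_MODEL = {
    "theta": ("total", "theta"),
    "a": ("mediator", "a"),
    "b": ("outcome", "b"),
    "c_prime": ("outcome", "c_prime"),
}


@dataclass
class EstimateSet:
    """Labelled estimates for one trial, keyed estimator -> parameter.

    Exactly one branch of labels is populated, determined by the stopping
    stage: {mle_1, pmle} after early stopping, {mle_all, mle_2, cmle}
    otherwise.  Adjusted estimators that failed to converge hold NaN with
    ``converged[(label, param)] = False``.
    """

    stop_stage: int
    estimates: dict[str, dict[str, float]] = field(default_factory=dict)
    converged: dict[tuple[str, str], bool] = field(default_factory=dict)

    def get(self, label: str, param: str) -> float:
        return self.estimates[label][param]

    def labels(self) -> tuple[str, ...]:
        return tuple(self.estimates)


@dataclass(frozen=True)
class SequentialSufficientStats:
    """Summary statistics feeding the adjusted estimators.

    ``z1`` is the observed stage-one standardized statistic for theta;
    ``info1 < info2`` are the information levels (per-arm ``n_k / (2
    sigma_hat^2)``); ``estimate_obs``/``se_obs`` are the target parameter's
    MLE and its standard error at the analysis stage; ``rho`` is the
    correlation between the target estimator and the theta estimator on
    common data (1 for theta itself).
    """

    z1: float
    info1: float
    info2: float
    estimate_obs: float
    se_obs: float
    rho: float = 1.0
    theta_obs: float | None = None  # theta MLE at the analysis stage
    se_theta: float | None = None  # its standard error

    def __post_init__(self) -> None:
        if not self.info1 < self.info2:
            raise ValueError("need info1 < info2")
        if not abs(self.rho) <= 1.0:
            raise ValueError("|rho| must not exceed 1")
        if not self.se_obs > 0:
            raise ValueError("se_obs must be positive")
        if self.rho != 1.0 and self.theta_obs is None:
            raise ValueError("secondary-parameter stats need theta_obs/se_theta")


def mle_estimates(data: pd.DataFrame, stop_stage: int) -> EstimateSet:
    """Unadjusted OLS estimates on the stage-appropriate record subsets.

    ``mle_1`` uses stage-one records only (early stop); ``mle_all`` pools
    both stages and ``mle_2`` uses stage-two records only (continuation).
    """
    if stop_stage == 1:
        subsets = {"mle_1": data[data["stage"] == 1]}
    elif stop_stage == 2:
        stage2 = data[data["stage"] == 2]
        if len(stage2) == 0:
            raise RuntimeError("stop_stage=2 but no stage-two records")
        subsets = {"mle_all": data, "mle_2": stage2}
    else:
        raise ValueError(f"stop_stage must be 1 or 2, got {stop_stage}")

    out = EstimateSet(stop_stage=stop_stage)
    for label, subset in subsets.items():
        fits = {
            "total": regression.fit_total_model(subset),
            "mediator": regression.fit_mediator_model(subset),
            "outcome": regression.fit_outcome_model(subset),
        }
        out.estimates[label] = {
            p: fits[model].estimate(coef) for p, (model, coef) in _PARAM_MODEL.items()
        }
        for p in PARAMS:
            out.converged[(label, p)] = True
    return out


# ---------------------------------------------------------------------------
# selection probabilities for the stopping event, on the mean scale m = theta*sqrt(I1)


def _log_p_continue(m: float, b1: float) -> float:
    """log P(|Z1| < b1) with Z1 ~ N(m, 1), numerically stable in the tails."""
    # P = Phi(b1 - m) - Phi(-b1 - m); factor the larger term out in log space
    la = float(log_ndtr(b1 - m))
    lb = float(log_ndtr(-b1 - m))
    diff = lb - la
    if diff >= 0.0:  # numerically degenerate: probability underflows
        return -math.inf
    return la + math.log1p(-math.exp(diff))


def _log_p_stop(m: float, b1: float) -> float:
    """log P(|Z1| >= b1) with Z1 ~ N(m, 1)."""
    return _logaddexp(float(log_ndtr(m - b1)), float(log_ndtr(-b1 - m)))


def _d2_log_p_stop(m: float, b1: float) -> float:
    """Second derivative of log P(|Z1| >= b1) w.r.t. the mean m."""
    p = math.exp(_log_p_stop(m, b1))
    d1 = _phi(m - b1) - _phi(m + b1)
    d2 = -(m - b1) * _phi(m - b1) + (m + b1) * _phi(m + b1)
    return d2 / p - (d1 / p) ** 2


# ---------------------------------------------------------------------------
# conditional MLE (continuation branch)


def _cond_loglik_theta_two_stage(
    theta: float, theta_all: float, info2: float, sqrt_i1: float, b1: float
) -> float:
    """Two-stage log-likelihood of theta conditional on |Z1| < b1.

    The unconditional part of the score-scale likelihood collapses to
    ``-I2 (theta - theta_all)^2 / 2`` (independent increments), and the
    continuation event only involves the stage-one mean ``theta * sqrt(I1)``.
    """
    return (
        -0.5 * info2 * (theta - theta_all) ** 2
        - _log_p_continue(theta * sqrt_i1, b1)
    )


def _cond_loglik_z1(theta: float, z1: float, sqrt_i1: float, b1: float, stopped: bool) -> float:
    """Stage-one log-likelihood of theta conditional on the stopping event."""
    m = theta * sqrt_i1
    base = -0.5 * (z1 - m) ** 2
    tail = _log_p_stop(m, b1) if stopped else _log_p_continue(m, b1)
    return base - tail


def _maximize(objective, center: float, halfwidth: float, xatol: float = 1e-9):
    """Bounded 1-D maximization; returns (argmax, converged)."""
    res = optimize.minimize_scalar(
        lambda t: -objective(t),
        bounds=(center - halfwidth, center + halfwidth),
        method="bounded",
        options={"xatol": xatol},
    )
    ok = bool(res.success) and np.isfinite(res.x) and np.isfinite(res.fun)
    return float(res.x), ok


def conditional_mle(stats: SequentialSufficientStats, boundary: float) -> tuple[float, bool]:
    """MLE conditional on continuation (|z1| < boundary).

    Returns ``(estimate, converged)``.  For theta the full two-stage
    conditional likelihood is maximized; for a secondary parameter the
    profiled bivariate construction described in the module docstring is
    used.
    """
    if abs(stats.z1) >= boundary:
        raise ValueError("conditional MLE requires a trial that continued")
    sqrt_i1 = math.sqrt(stats.info1)
    theta_obs = stats.theta_obs if stats.theta_obs is not None else stats.estimate_obs
    se_theta = (
        stats.se_theta if stats.se_theta is not None else 1.0 / math.sqrt(stats.info2)
    )
    obj = lambda t: _cond_loglik_theta_two_stage(
        t, theta_obs, stats.info2, sqrt_i1, boundary
    )
    theta_tilde, ok = _maximize(obj, theta_obs, 10.0 * se_theta)
    if stats.rho == 1.0:  # theta itself
        return theta_tilde, ok
    if not ok:
        return float("nan"), False
    est = stats.estimate_obs - stats.rho * (stats.se_obs / se_theta) * (
        theta_obs - theta_tilde
    )
    return float(est), True


def penalized_mle(stats: SequentialSufficientStats, boundary: float) -> tuple[float, bool]:
    """Firth-type penalized MLE after early stopping (|z1| >= boundary).

    Maximizes ``l_c(theta) + 0.5 * log I_c(theta)`` where ``l_c`` is the
    stage-one likelihood truncated to the stopping event and ``I_c`` its
    observed information (computed analytically).  Regions where the
    truncated information is nonpositive are excluded; an optimizer failure
    or an all-nonpositive window is reported as non-convergence so the
    replication can be discarded and counted.
    """
    if abs(stats.z1) < boundary:
        raise ValueError("penalized MLE requires a trial that stopped early")
    sqrt_i1 = math.sqrt(stats.info1)

    def penalized_profile(theta: float) -> float:
        m = theta * sqrt_i1
        info_c = stats.info1 * (1.0 + _d2_log_p_stop(m, boundary))
        if not (info_c > 0.0 and np.isfinite(info_c)):
            return -np.inf
        return _cond_loglik_z1(theta, stats.z1, sqrt_i1, boundary, stopped=True) + 0.5 * math.log(
            info_c
        )

    theta_obs = stats.theta_obs if stats.theta_obs is not None else stats.z1 / sqrt_i1
    se_theta = stats.se_theta if stats.se_theta is not None else 1.0 / sqrt_i1
    theta_tilde, ok = _maximize(penalized_profile, theta_obs, 10.0 * se_theta)
    if not (ok and np.isfinite(penalized_profile(theta_tilde))):
        return float("nan"), False
    if stats.rho == 1.0:  # theta itself
        return theta_tilde, True
    est = stats.estimate_obs - stats.rho * (stats.se_obs / se_theta) * (
        theta_obs - theta_tilde
    )
    return float(est), True


def secondary_correlation(fits: dict[str, regression.FitResult], target: str) -> float:
    """Plug-in correlation between the target estimator and theta-hat.

    For ``a`` the model implies ``rho = b sigma_m / sqrt(b^2 sigma_m^2 +
    sigma_y^2)``; for ``c'`` the covariance with theta-hat follows from the
    exact decomposition ``theta_hat = c'_hat + a_hat b_hat`` with
    ``cov(a_hat, c'_hat) = 0``.  The result is clamped to [-0.999, 0.999].
    """
    total, mediator, outcome = fits["total"], fits["mediator"], fits["outcome"]
    b_hat = outcome.estimate("b")
    sm2 = mediator.resid_var
    sy2 = outcome.resid_var
    if not (sm2 > 0 and sy2 > 0 and total.se("theta") > 0):
        raise ValueError("degenerate variance estimates")
    if target == "a":
        rho = b_hat * math.sqrt(sm2) / math.sqrt(b_hat**2 * sm2 + sy2)
    elif target == "c_prime":
        i_c = outcome.names.index("c_prime")
        i_b = outcome.names.index("b")
        var_c = outcome.cov_params[i_c, i_c]
        cov_cb = outcome.cov_params[i_c, i_b]
        a_hat = mediator.estimate("a")
        cov_theta_c = var_c + a_hat * cov_cb
        rho = cov_theta_c / (total.se("theta") * math.sqrt(var_c))
    else:
        raise ValueError(f"no adjusted estimator is defined for {target!r}")
    return float(np.clip(rho, -0.999, 0.999))
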
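"""Statsmodels-style model object for analysing one two-stage trial.

:class:`GroupSequentialMediation` binds one trial's records to a resolved
:class:`~gsmediate.design.GSDesign`; :meth:`~GroupSequentialMediation.fit`
runs the full interim + final analysis protocol and returns a
:class:`GroupSequentialMediationResults` carrying the stopping decision, the
regression fits, all hypothesis-test decisions and the estimator menu.

Protocol
--------
1. Fit the total-effect model to the stage-one records; stop for efficacy iff
   the t-statistic crosses the Pocock boundary.
2. The analysis set is the stage-one data if stopped, all data otherwise; the
   total-effect test (H01) uses the boundary at either stage.
3. The direct-effect t-test (H02) and the four indirect-effect procedures
   (H03) run on the analysis set at the 5% level regardless of stage.
4. The estimator menu is branch-specific: {mle_1, pmle} after early stopping,
   {mle_all, mle_2, cmle} after continuation; ``b`` is never adjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimators, hypotests, regression
from .design import GSDesign
from .estimators import EstimateSet, SequentialSufficientStats
from .hypotests import TestResult

__all__ = ["GroupSequentialMediation", "GroupSequentialMediationResults"]

_ADJUSTED_PARAMS = ("theta", "a", "c_prime")  # b is exempt from adjustment


class GroupSequentialMediation:
    """Mediation analysis of one trial run under a two-stage design.

    Parameters
    ----------
    data : pandas.DataFrame
        Per-subject records with columns ``arm`` (0/1), ``mediator``,
        ``outcome`` and ``stage`` (1/2).
    design : GSDesign
        The resolved two-stage design the trial was run under.
    alpha : float
        Significance level of the secondary tests (H02, H03).
    mc_draws : int
        Draws for the Monte-Carlo confidence-interval test of the indirect
        effect.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        design: GSDesign,
        alpha: float = 0.05,
        mc_draws: int = 20_000,
    ) -> None:
        required = {"arm", "mediator", "outcome", "stage"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data lacks required columns: {sorted(missing)}")
        self.data = data
        self.design = design
        self.alpha = alpha
        self.mc_draws = mc_draws

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, design: GSDesign, **kwargs
    ) -> "GroupSequentialMediation":
        return cls(data, design, **kwargs)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        rng: np.random.Generator | None = None,
        compute_adjusted: bool = True,
    ) -> "GroupSequentialMediationResults":
        """Run the interim and final analysis; return the results object.

        ``rng`` seeds the Monte-Carlo CI test; pass one for reproducibility.
        ``compute_adjusted=False`` skips the pmle/cmle optimizations (the
        test decisions and unadjusted estimates are unaffected).
        """
        if rng is None:
            rng = np.random.default_rng()
        design = self.design
        b1 = design.boundary
        stage1 = self.data[self.data["stage"] == 1]

        interim_fit = regression.fit_total_model(stage1)
        z1 = interim_fit["theta"]["t"]
        stop_stage = 1 if abs(z1) >= b1 else 2

        analysis_data = stage1 if stop_stage == 1 else self.data
        fits = {
            "total": regression.fit_total_model(analysis_data),
            "mediator": regression.fit_mediator_model(analysis_data),
            "outcome": regression.fit_outcome_model(analysis_data),
        }

        tests = self._run_tests(fits, z1, stop_stage, rng)
        estimates = estimators.mle_estimates(self.data, stop_stage)
        if compute_adjusted:
            self._add_adjusted(estimates, fits, z1, stop_stage)

        return GroupSequentialMediationResults(
            model=self,
            stop_stage=stop_stage,
            z1=float(z1),
            fits=fits,
            tests=tests,
            estimates=estimates,
        )

    # -- internals ----------------------------------------------------------

    def _run_tests(self, fits, z1, stop_stage, rng) -> list[TestResult]:
        alpha = self.alpha
        b1 = self.design.boundary
        t_final = fits["total"]["theta"]["t"]
        h01_stat = z1 if stop_stage == 1 else t_final
        tests = [
            TestResult(
                "H01",
                "gsd-boundary",
                reject=bool(abs(h01_stat) >= b1),
                statistic=float(h01_stat),
                stage=stop_stage,
            )
        ]
        h02 = hypotests.direct_effect_test(fits["outcome"], alpha)
        tests.append(
            TestResult(**{**h02.__dict__, "stage": stop_stage})
        )

        a_row = fits["mediator"]["a"]
        b_row = fits["outcome"]["b"]
        for order in (1, 2):
            res = hypotests.sobel_test(
                a_row["estimate"], a_row["se"], b_row["estimate"], b_row["se"],
                order=order, alpha=alpha,
            )
            tests.append(TestResult(**{**res.__dict__, "stage": stop_stage}))
        res = hypotests.joint_significance_test(a_row["p"], b_row["p"], alpha)
        tests.append(TestResult(**{**res.__dict__, "stage": stop_stage}))
        res = hypotests.monte_carlo_ci_test(
            a_row["estimate"], a_row["se"], b_row["estimate"], b_row["se"],
            alpha=alpha, n_draws=self.mc_draws, rng=rng,
        )
        tests.append(TestResult(**{**res.__dict__, "stage": stop_stage}))
        return tests

    def _sufficient_stats(self, fits, z1, stop_stage, param) -> SequentialSufficientStats:
        design = self.design
        n1, n2 = design.n_stage1_per_arm, design.n_max_per_arm
        # information plug-in from the analysis-stage total-model fit
        sigma2 = fits["total"].resid_var
        info1, info2 = n1 / (2.0 * sigma2), n2 / (2.0 * sigma2)
        if param == "theta":
            rho = 1.0
            model, coef = "total", "theta"
        else:
            rho = estimators.secondary_correlation(fits, param)
            model, coef = ("mediator", "a") if param == "a" else ("outcome", "c_prime")
        return SequentialSufficientStats(
            z1=float(z1),
            info1=info1,
            info2=info2,
            estimate_obs=fits[model].estimate(coef),
            se_obs=fits[model].se(coef),
            rho=rho,
            theta_obs=fits["total"].estimate("theta"),
            se_theta=fits["total"].se("theta"),
        )

    def _add_adjusted(self, estimates: EstimateSet, fits, z1, stop_stage) -> None:
        b1 = self.design.boundary
        label = "pmle" if stop_stage == 1 else "cmle"
        adjust = estimators.penalized_mle if stop_stage == 1 else estimators.conditional_mle
        estimates.estimates[label] = {}
        for param in _ADJUSTED_PARAMS:
            stats = self._sufficient_stats(fits, z1, stop_stage, param)
            try:
                est, ok = adjust(stats, b1)
            except (ValueError, RuntimeError):
                est, ok = float("nan"), False
            estimates.estimates[label][param] = est if ok else float("nan")
            estimates.converged[(label, param)] = ok


@dataclass
class GroupSequentialMediationResults:
    """Results of one trial's mediation analysis under the design."""

    model: GroupSequentialMediation
    stop_stage: int
    z1: float
    fits: dict[str, regression.FitResult]
    tests: list[TestResult]
    estimates: EstimateSet

    @property
    def stopped_early(self) -> bool:
        return self.stop_stage == 1

    def test(self, hypothesis: str, method: str | None = None) -> TestResult:
        for t in self.tests:
            if t.hypothesis == hypothesis and (method is None or t.method == method):
                return t
        raise KeyError(f"no test recorded for {hypothesis}/{method}")

    def estimates_frame(self) -> pd.DataFrame:
        rows = []
        for label, vals in self.estimates.estimates.items():
            for param, v in vals.items():
                rows.append(
                    {
                        "estimator": label,
                        "parameter": param,
                        "estimate": v,
                        "converged": self.estimates.converged.get((label, param), True),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        d = self.model.design
        lines = [
            "Group-sequential mediation analysis",
            "=" * 51,
            f"Design: alpha={d.alpha}, boundary={d.boundary:.4f}, "
            f"n/arm={d.n_max_per_arm} (interim {d.n_stage1_per_arm})",
            f"Stage-1 statistic z1 = {self.z1:+.4f}  ->  "
            + ("stopped early for efficacy" if self.stopped_early else "continued to stage 2"),
            "",
            "Tests",
            "-" * 51,
            f"{'hypothesis':<12}{'method':<14}{'statistic':>10}{'p':>9}  reject",
        ]
        for t in self.tests:
            stat = f"{t.statistic:.4f}" if t.statistic is not None else "-"
            p = f"{t.p_value:.4f}" if t.p_value is not None else "-"
            lines.append(
                f"{t.hypothesis:<12}{t.method:<14}{stat:>10}{p:>9}  {t.reject}"
            )
        lines += ["", "Estimates", "-" * 51,
                  f"{'estimator':<10}" + "".join(f"{p:>10}" for p in estimators.PARAMS)]
        for label, vals in self.estimates.estimates.items():
            cells = []
            for p in estimators.PARAMS:
                v = vals.get(p)
                cells.append(f"{v:>10.4f}" if v is not None and np.isfinite(v) else f"{'-':>10}")
            lines.append(f"{label:<10}" + "".join(cells))
        return "\n".join(lines)
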
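"""Monte-Carlo engine: replicate trials and compute operating characteristics.

`run_study` loops :func:`run_single_trial` over independent replication
substreams and aggregates

* rejection rates per hypothesis x method, split by stopping stage (the
  stage-one and stage-two rates sum to the overall power / type-I error);
* stopping frequencies;
* conditional bias per estimator x parameter, reported only for stopping
  strata with at least 1000 replications (under-sampled strata are flagged),
  with non-convergent adjusted estimates discarded and counted.

`run_fixed_design_study` is the single-look comparator: every test at the
nominal level on the full sample, no stopping, no adjusted estimators.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from . import hypotests, regression
from .design import GSDesign, make_design
from .estimators import PARAMS, EstimateSet
from .hypotests import TestResult
from .mechanism import (
    MediationParams,
    ScenarioSpec,
    get_scenario,
    simulate_trial_data,
)
from .model import GroupSequentialMediation

logger = logging.getLogger(__name__)

__all__ = [
    "TrialResult",
    "PerformanceSummary",
    "run_single_trial",
    "run_study",
    "run_fixed_design_study",
    "summarize_bias",
    "write_results",
    "read_results",
    "read_config",
]

#: frozen column schema of the tidy results CSV
RESULT_COLUMNS = [
    "kind",
    "hypothesis",
    "method",
    "estimator",
    "parameter",
    "stage",
    "value",
    "mc_se",
    "n",
    "n_discarded",
    "flag",
]

_MIN_STRATUM = 1000  # replications required before a conditional bias is reported


@dataclass
class TrialResult:
    """One replication: stopping stage, test decisions and estimates."""

    stop_stage: int
    z1: float
    tests: list[TestResult]
    estimates: EstimateSet
    seed_id: int


@dataclass
class PerformanceSummary:
    """Aggregated operating characteristics of a study."""

    rejection: pd.DataFrame  # hypothesis, method, stage-wise + overall rates
    stop_frequencies: tuple[int, int, int]  # (n_stop1, n_stop2, n_total)
    bias: pd.DataFrame | None
    metadata: dict

    def rejection_rate(self, hypothesis: str, method: str, stage: str = "overall") -> float:
        df = self.rejection
        row = df[(df.hypothesis == hypothesis) & (df.method == method)]
        if row.empty:
            raise KeyError(f"no rejection row for {hypothesis}/{method}")
        return float(row.iloc[0][f"reject_rate_{stage}"])

    def bias_value(self, estimator: str, parameter: str) -> float:
        row = self.bias[
            (self.bias.estimator == estimator) & (self.bias.parameter == parameter)
        ]
        if row.empty:
            raise KeyError(f"no bias row for {estimator}/{parameter}")
        return float(row.iloc[0]["bias"])

    def bias_row(self, estimator: str, parameter: str) -> pd.Series:
        row = self.bias[
            (self.bias.estimator == estimator) & (self.bias.parameter == parameter)
        ]
        if row.empty:
            raise KeyError(f"no bias row for {estimator}/{parameter}")
        return row.iloc[0]

    # -- presentation -------------------------------------------------------

    def plot_rejection(self, ax=None):
        """Bar chart of stage-wise rejection rates per hypothesis/method."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        df = self.rejection
        labels = df.hypothesis + "/" + df.method
        ax.bar(labels, df.reject_rate_stage1, label="stage 1")
        ax.bar(labels, df.reject_rate_stage2, bottom=df.reject_rate_stage1, label="stage 2")
        ax.set_ylabel("rejection rate")
        ax.tick_params(axis="x", rotation=45)
        ax.legend()
        return ax

    def plot_bias(self, ax=None):
        """Conditional bias per estimator x parameter with 3-MC-SE bars."""
        import matplotlib.pyplot as plt

        if self.bias is None or self.bias.empty:
            raise ValueError("no bias table in this summary")
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        df = self.bias.dropna(subset=["bias"])
        labels = df.estimator + ":" + df.parameter
        ax.errorbar(labels, df.bias, yerr=3 * df.mc_se, fmt="o", capsize=3)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_ylabel("conditional bias")
        ax.tick_params(axis="x", rotation=45)
        return ax


def run_single_trial(
    design: GSDesign,
    params: MediationParams,
    rng: np.random.Generator,
    alpha: float = 0.05,
    mc_draws: int = 20_000,
    compute_adjusted: bool = True,
    seed_id: int = 0,
) -> TrialResult:
    """Simulate one trial under the design and run the full analysis."""
    data = simulate_trial_data(
        params, design.n_max_per_arm, design.n_stage1_per_arm, rng
    )
    model = GroupSequentialMediation(data, design, alpha=alpha, mc_draws=mc_draws)
    res = model.fit(rng=rng, compute_adjusted=compute_adjusted)
    return TrialResult(
        stop_stage=res.stop_stage,
        z1=res.z1,
        tests=res.tests,
        estimates=res.estimates,
        seed_id=seed_id,
    )


def _aggregate_rejections(
    counts: dict[tuple[str, str], np.ndarray], n_total: int
) -> pd.DataFrame:
    rows = []
    for (hyp, method), c in sorted(counts.items()):
        r1, r2 = c[0] / n_total, c[1] / n_total
        overall = r1 + r2
        rows.append(
            {
                "hypothesis": hyp,
                "method": method,
                "reject_rate_stage1": r1,
                "reject_rate_stage2": r2,
                "reject_rate_overall": overall,
                "mc_se": float(np.sqrt(max(overall * (1 - overall), 0.0) / n_total)),
                "n": n_total,
            }
        )
    return pd.DataFrame(rows)


def summarize_bias(records: pd.DataFrame, truth: MediationParams) -> pd.DataFrame:
    """Conditional mean bias per estimator x parameter x stopping stage.

    ``records`` has one row per replication x estimator x parameter with
    columns ``estimator, parameter, stop_stage, estimate, converged``.
    Non-convergent rows are discarded and counted; strata with fewer than
    1000 surviving replications are flagged ``under_sampled`` and strata with
    none report an absent (NaN) bias.
    """
    true_vals = truth.truth()
    rows = []
    for (est, param, stage), grp in records.groupby(
        ["estimator", "parameter", "stop_stage"], sort=True
    ):
        ok = grp[grp.converged & np.isfinite(grp.estimate)]
        n_disc = len(grp) - len(ok)
        n = len(ok)
        if n == 0:
            bias, se = float("nan"), float("nan")
        else:
            err = ok.estimate.to_numpy() - true_vals[param]
            bias = float(err.mean())
            se = float(err.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append(
            {
                "estimator": est,
                "parameter": param,
                "stop_stage": int(stage),
                "bias": bias,
                "mc_se": se,
                "n": n,
                "n_discarded": n_disc,
                "under_sampled": n < _MIN_STRATUM,
            }
        )
    return pd.DataFrame(rows)


def run_study(
    design: GSDesign,
    scenario: ScenarioSpec | MediationParams | str,
    n_reps: int,
    master_seed: int,
    alpha: float = 0.05,
    mc_draws: int = 20_000,
    compute_adjusted: bool = True,
) -> PerformanceSummary:
    """Replicate the trial ``n_reps`` times and aggregate performance.

    Each replication uses an independent substream spawned from
    ``master_seed``, so any single replication can be regenerated in
    isolation and the whole study is reproducible.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    params = scenario.params if isinstance(scenario, ScenarioSpec) else scenario
    name = scenario.name if isinstance(scenario, ScenarioSpec) else "custom"

    children = np.random.SeedSequence(master_seed).spawn(n_reps)
    counts: dict[tuple[str, str], np.ndarray] = {}
    stop_counts = np.zeros(2, dtype=int)
    est_rows: list[dict] = []
    n_failures = 0

    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            tr = run_single_trial(
                design,
                params,
                rng,
                alpha=alpha,
                mc_draws=mc_draws,
                compute_adjusted=compute_adjusted,
                seed_id=i,
            )
        except Exception:  # capture, never abort the loop
            n_failures += 1
            logger.warning("replication %d failed", i, exc_info=True)
            continue
        stop_counts[tr.stop_stage - 1] += 1
        for t in tr.tests:
            key = (t.hypothesis, t.method)
            if key not in counts:
                counts[key] = np.zeros(2, dtype=int)
            if t.reject:
                counts[key][tr.stop_stage - 1] += 1
        for label, vals in tr.estimates.estimates.items():
            for p, v in vals.items():
                est_rows.append(
                    {
                        "estimator": label,
                        "parameter": p,
                        "stop_stage": tr.stop_stage,
                        "estimate": v,
                        "converged": tr.estimates.converged.get((label, p), True),
                    }
                )
        if (i + 1) % 2000 == 0:
            logger.info("study %s: %d/%d replications done", name, i + 1, n_reps)

    n_done = int(stop_counts.sum())
    rejection = _aggregate_rejections(counts, n_done)
    bias = summarize_bias(pd.DataFrame(est_rows), params) if est_rows else None
    metadata = {
        "design": {
            "alpha": design.alpha,
            "boundary": design.boundary,
            "info_fraction": design.info_fraction,
            "n_max_per_arm": design.n_max_per_arm,
            "n_stage1_per_arm": design.n_stage1_per_arm,
        },
        "scenario": name,
        "params": {
            "a": params.a,
            "b": params.b,
            "c_prime": params.c_prime,
            "i_m": params.i_m,
            "i_y": params.i_y,
            "sigma_m": params.sigma_m,
            "sigma_y": params.sigma_y,
        },
        "n_reps": n_reps,
        "n_failures": n_failures,
        "master_seed": master_seed,
        "alpha_secondary": alpha,
        "mc_draws": mc_draws,
        "version": _pkg_version,
        "design_kind": "group-sequential",
    }
    return PerformanceSummary(
        rejection=rejection,
        stop_frequencies=(int(stop_counts[0]), int(stop_counts[1]), n_done),
        bias=bias,
        metadata=metadata,
    )


def run_fixed_design_study(
    n_per_arm: int,
    scenario: ScenarioSpec | MediationParams | str,
    n_reps: int,
    master_seed: int,
    alpha: float = 0.05,
    mc_draws: int = 20_000,
) -> PerformanceSummary:
    """Single-look comparator: all tests at the nominal level on the full
    sample; no interim, no stopping, no adjusted estimators."""
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    params = scenario.params if isinstance(scenario, ScenarioSpec) else scenario
    name = scenario.name if isinstance(scenario, ScenarioSpec) else "custom"

    children = np.random.SeedSequence(master_seed).spawn(n_reps)
    counts: dict[tuple[str, str], np.ndarray] = {}
    est_rows: list[dict] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        data = simulate_trial_data(params, n_per_arm, max(1, n_per_arm // 2), rng)
        fits = {
            "total": regression.fit_total_model(data),
            "mediator": regression.fit_mediator_model(data),
            "outcome": regression.fit_outcome_model(data),
        }
        theta_row = fits["total"]["theta"]
        a_row, b_row = fits["mediator"]["a"], fits["outcome"]["b"]
        tests = [
            TestResult("H01", "t-test", reject=bool(theta_row["p"] < alpha),
                       statistic=theta_row["t"], p_value=theta_row["p"], stage=1),
            hypotests.direct_effect_test(fits["outcome"], alpha),
            hypotests.sobel_test(a_row["estimate"], a_row["se"],
                                 b_row["estimate"], b_row["se"], 1, alpha),
            hypotests.sobel_test(a_row["estimate"], a_row["se"],
                                 b_row["estimate"], b_row["se"], 2, alpha),
            hypotests.joint_significance_test(a_row["p"], b_row["p"], alpha),
            hypotests.monte_carlo_ci_test(
                a_row["estimate"], a_row["se"], b_row["estimate"], b_row["se"],
                alpha, mc_draws, rng,
            ),
        ]
        for t in tests:
            key = (t.hypothesis, t.method)
            if key not in counts:
                counts[key] = np.zeros(2, dtype=int)
            if t.reject:
                counts[key][0] += 1
        for p, (model, coef) in (
            ("theta", ("total", "theta")),
            ("a", ("mediator", "a")),
            ("b", ("outcome", "b")),
            ("c_prime", ("outcome", "c_prime")),
        ):
            est_rows.append(
                {
                    "estimator": "mle",
                    "parameter": p,
                    "stop_stage": 1,
                    "estimate": fits[model].estimate(coef),
                    "converged": True,
                }
            )
    rejection = _aggregate_rejections(counts, n_reps)
    bias = summarize_bias(pd.DataFrame(est_rows), params)
    metadata = {
        "design": {"n_per_arm": n_per_arm},
        "scenario": name,
        "n_reps": n_reps,
        "n_failures": 0,
        "master_seed": master_seed,
        "alpha_secondary": alpha,
        "mc_draws": mc_draws,
        "version": _pkg_version,
        "design_kind": "fixed",
    }
    return PerformanceSummary(
        rejection=rejection,
        stop_frequencies=(n_reps, 0, n_reps),
        bias=bias,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# results / config I/O


def _tidy_frame(summary: PerformanceSummary) -> pd.DataFrame:
    rows = []
    for _, r in summary.rejection.iterrows():
        for stage, col in (("1", "reject_rate_stage1"), ("2", "reject_rate_stage2"),
                           ("overall", "reject_rate_overall")):
            rows.append(
                {
                    "kind": "rejection",
                    "hypothesis": r.hypothesis,
                    "method": r.method,
                    "estimator": "",
                    "parameter": "",
                    "stage": stage,
                    "value": r[col],
                    "mc_se": r.mc_se if stage == "overall" else "",
                    "n": int(r.n),
                    "n_discarded": "",
                    "flag": "",
                }
            )
    n1, n2, nt = summary.stop_frequencies
    for stage, count in (("1", n1), ("2", n2)):
        rows.append(
            {
                "kind": "stopping",
                "hypothesis": "",
                "method": "",
                "estimator": "",
                "parameter": "",
                "stage": stage,
                "value": count / nt if nt else float("nan"),
                "mc_se": "",
                "n": nt,
                "n_discarded": "",
                "flag": "",
            }
        )
    if summary.bias is not None:
        for _, r in summary.bias.iterrows():
            rows.append(
                {
                    "kind": "bias",
                    "hypothesis": "",
                    "method": "",
                    "estimator": r.estimator,
                    "parameter": r.parameter,
                    "stage": str(int(r.stop_stage)),
                    "value": r.bias,
                    "mc_se": r.mc_se,
                    "n": int(r.n),
                    "n_discarded": int(r.n_discarded),
                    "flag": "under_sampled" if r.under_sampled else "",
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(summary: PerformanceSummary, path) -> None:
    """Serialize a summary as a tidy CSV plus a JSON metadata sidecar."""
    path = Path(path)
    try:
        _tidy_frame(summary).to_csv(path, index=False)
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(summary.metadata, fh, indent=2, sort_keys=True)
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc


def read_results(path) -> PerformanceSummary:
    """Inverse of :func:`write_results`."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"stage": str}, keep_default_na=False,
                     na_values=["nan"])
    if list(df.columns) != RESULT_COLUMNS:
        raise ValueError(f"unexpected results schema in {path}")
    with open(path.with_suffix(path.suffix + ".meta.json")) as fh:
        metadata = json.load(fh)

    rej = df[df.kind == "rejection"]
    rows = []
    for (hyp, method), grp in rej.groupby(["hypothesis", "method"], sort=True):
        by_stage = {r.stage: r for r in grp.itertuples()}
        rows.append(
            {
                "hypothesis": hyp,
                "method": method,
                "reject_rate_stage1": float(by_stage["1"].value),
                "reject_rate_stage2": float(by_stage["2"].value),
                "reject_rate_overall": float(by_stage["overall"].value),
                "mc_se": float(by_stage["overall"].mc_se),
                "n": int(by_stage["overall"].n),
            }
        )
    rejection = pd.DataFrame(rows)

    stop = df[df.kind == "stopping"]
    nt = int(stop.iloc[0].n)
    freqs = {r.stage: int(round(float(r.value) * nt)) for r in stop.itertuples()}
    stop_frequencies = (freqs["1"], freqs["2"], nt)

    bias_df = df[df.kind == "bias"]
    bias = None
    if not bias_df.empty:
        bias = pd.DataFrame(
            {
                "estimator": bias_df.estimator.to_numpy(),
                "parameter": bias_df.parameter.to_numpy(),
                "stop_stage": bias_df.stage.astype(int).to_numpy(),
                "bias": pd.to_numeric(bias_df.value).to_numpy(),
                "mc_se": pd.to_numeric(bias_df.mc_se).to_numpy(),
                "n": bias_df.n.astype(int).to_numpy(),
                "n_discarded": bias_df.n_discarded.astype(int).to_numpy(),
                "under_sampled": (bias_df.flag == "under_sampled").to_numpy(),
            }
        )
    return PerformanceSummary(
        rejection=rejection,
        stop_frequencies=stop_frequencies,
        bias=bias,
        metadata=metadata,
    )


_CONFIG_DEFAULTS = {
    "alpha": 0.05,
    "power": 0.9,
    "info_fraction": 0.5,
    "n_per_arm": None,
    "scenario": None,
    "params": None,
    "n_reps": 10_000,
    "master_seed": 0,
    "mc_draws": 20_000,
    "compute_adjusted": True,
}


def read_config(path) -> dict:
    """Load a study configuration (YAML or JSON) with defaults filled in."""
    path = Path(path)
    try:
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    except (OSError, ValueError, yaml.YAMLError) as exc:
        raise ValueError(f"malformed or unreadable config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(raw) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**_CONFIG_DEFAULTS, **raw}
    if cfg["scenario"] is None and cfg["params"] is None:
        raise ValueError("config must set either 'scenario' or 'params'")
    return cfg


def run_from_config(cfg: dict) -> PerformanceSummary:
    """Execute the study a config mapping describes."""
    if cfg.get("params") is not None:
        scenario = MediationParams(**cfg["params"])
        n_per_arm = cfg["n_per_arm"]
    else:
        spec = get_scenario(cfg["scenario"])
        scenario = spec
        n_per_arm = cfg["n_per_arm"] or spec.n_per_arm
    design = make_design(
        alpha=cfg["alpha"],
        power=cfg["power"],
        info_fraction=cfg["info_fraction"],
        n_max_per_arm=n_per_arm,
    )
    return run_study(
        design,
        scenario,
        n_reps=cfg["n_reps"],
        master_seed=cfg["master_seed"],
        alpha=cfg["alpha"],
        mc_draws=cfg["mc_draws"],
        compute_adjusted=cfg["compute_adjusted"],
    )
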
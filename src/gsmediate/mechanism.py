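"""Linear mediation mechanism: truth arithmetic and the synthetic trial
generator.

The data-generating mechanism is the standard single-mediator linear system

    M = i_m + a X + e_m,   e_m ~ N(0, sigma_m^2)
    Y = i_y + c' X + b M + e_y,   e_y ~ N(0, sigma_y^2)

with independent errors, binary randomization X in {0, 1} and equal arms.
The indirect effect is a*b, the direct effect c', and the total
(intention-to-treat) effect theta = a*b + c'.  Because the mediator inflates
the marginal outcome variance to ``b^2 sigma_m^2 + sigma_y^2``, the
standardized effect the trial actually operates at is the adjusted effect
size ``(a b + c') / sqrt(b^2 sigma_m^2 + sigma_y^2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MediationParams",
    "ScenarioSpec",
    "total_effect",
    "adjusted_effect_size",
    "simulate_trial_data",
    "scenario_registry",
    "get_scenario",
    "registry_to_yaml",
    "registry_from_yaml",
]


@dataclass(frozen=True)
class MediationParams:
    """True path coefficients and error scales of the mediation system."""

    a: float
    b: float
    c_prime: float
    i_m: float = -0.4
    i_y: float = -0.4
    sigma_m: float = 1.0
    sigma_y: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sigma_m > 0.0 and self.sigma_y > 0.0):
            raise ValueError("error standard deviations must be positive")

    @property
    def theta(self) -> float:
        return total_effect(self)

    @property
    def outcome_sd(self) -> float:
        """Marginal SD of Y within an arm: sqrt(b^2 sigma_m^2 + sigma_y^2)."""
        return math.sqrt(self.b**2 * self.sigma_m**2 + self.sigma_y**2)

    def truth(self) -> dict[str, float]:
        """True values keyed by the parameter names used in reports."""
        return {
            "theta": self.theta,
            "a": self.a,
            "b": self.b,
            "c_prime": self.c_prime,
        }


def total_effect(params: MediationParams) -> float:
    """Total (intention-to-treat) effect theta = a*b + c'."""
    return params.a * params.b + params.c_prime


def adjusted_effect_size(params: MediationParams) -> float:
    """Standardized total effect, ``(a b + c') / sqrt(b^2 sigma_m^2 + sigma_y^2)``.

    This is the effect size a sample-size calculation must use when the
    outcome variance is partly generated by the mediator.
    """
    return total_effect(params) / params.outcome_sd


def simulate_trial_data(
    params: MediationParams,
    n_per_arm: int,
    n_stage1_per_arm: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate one trial of ``2 * n_per_arm`` subjects.

    Allocation is deterministic and exactly balanced within each stage
    (the analogue of block randomization with blocks of size two): the first
    ``n_stage1_per_arm`` subjects per arm belong to stage 1, the remainder to
    stage 2.

    Returns a DataFrame with columns ``arm`` (0/1), ``mediator``, ``outcome``
    and ``stage`` (1/2).
    """
    if not (0 < n_stage1_per_arm < n_per_arm):
        raise ValueError(
            f"need 0 < n_stage1_per_arm < n_per_arm, got {n_stage1_per_arm}, {n_per_arm}"
        )
    n1, n2 = n_stage1_per_arm, n_per_arm - n_stage1_per_arm
    arm = np.concatenate(
        [np.repeat([0, 1], n1), np.repeat([0, 1], n2)]
    ).astype(np.int8)
    stage = np.concatenate(
        [np.ones(2 * n1, dtype=np.int8), np.full(2 * n2, 2, dtype=np.int8)]
    )
    x = arm.astype(float)
    m = params.i_m + params.a * x + params.sigma_m * rng.standard_normal(x.size)
    y = (
        params.i_y
        + params.c_prime * x
        + params.b * m
        + params.sigma_y * rng.standard_normal(x.size)
    )
    return pd.DataFrame(
        {"arm": arm, "mediator": m, "outcome": y, "stage": stage}
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """A named simulation scenario: true parameters plus study defaults."""

    name: str
    params: MediationParams
    n_reps: int = 10_000
    n_per_arm: int = 191
    reconstructed: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        d["params"] = MediationParams(**d["params"])
        return cls(**d)


# (a, b) pairs of the effect-size grid columns, in table order:
# four cells varying a with b = 0, then three varying b with a = 0.
_GRID_AB = [
    (0.0, 0.0),
    (0.14, 0.0),
    (0.39, 0.0),
    (0.59, 0.0),
    (0.0, 0.14),
    (0.0, 0.39),
    (0.0, 0.59),
]

# 0.59^2; grid cells quoting "c' = 0.59^2" use this numeric value.
_C59SQ = 0.3481


def _build_registry() -> dict[str, ScenarioSpec]:
    reg: dict[str, ScenarioSpec] = {}

    def add(name, a, b, c, sigma_m=1.0, n_per_arm=191, reconstructed=False):
        reg[name] = ScenarioSpec(
            name=name,
            params=MediationParams(a=a, b=b, c_prime=c, sigma_m=sigma_m),
            n_per_arm=n_per_arm,
            reconstructed=reconstructed,
        )

    for j, (a, b) in enumerate(_GRID_AB, start=1):
        for sm, suffix in ((1.0, ""), (1.5, "-sm1.5")):
            add(f"Tab1-col{j}{suffix}", a, b, 0.0, sigma_m=sm)
            add(f"Tab2-col{j}{suffix}", a, b, _C59SQ, sigma_m=sm)
    for sm, suffix in ((1.0, ""), (1.5, "-sm1.5")):
        add(f"Tab2-col8{suffix}", 0.59, 0.59, 0.0, sigma_m=sm)

    # S1-S6: two (a, b) pairs fixing the indirect effect at 0.39 * 0.14,
    # crossed with c' in {0, 0.14, 0.39}.  Reconstructed from the in-text
    # anchors (S1/S5 stopping frequencies, S2 theta ~ 0.055, S6 ~5%
    # continuation); overridable through the YAML registry.
    s_grid = {
        "S1": (0.39, 0.14, 0.0),
        "S2": (0.14, 0.39, 0.0),
        "S3": (0.39, 0.14, 0.14),
        "S4": (0.14, 0.39, 0.14),
        "S5": (0.39, 0.14, 0.39),
        "S6": (0.14, 0.39, 0.39),
    }
    for name, (a, b, c) in s_grid.items():
        add(name, a, b, c, reconstructed=True)
    return reg


def scenario_registry() -> dict[str, ScenarioSpec]:
    """All named scenarios: the effect-size grid cells plus S1-S6."""
    return _build_registry()


def get_scenario(name: str) -> ScenarioSpec:
    reg = scenario_registry()
    try:
        return reg[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; known: {sorted(reg)}"
        ) from None


def registry_to_yaml(reg: dict[str, ScenarioSpec], path) -> None:
    payload = {name: spec.to_dict() for name, spec in reg.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def registry_from_yaml(path) -> dict[str, ScenarioSpec]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {name: ScenarioSpec.from_dict(d) for name, d in payload.items()}
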
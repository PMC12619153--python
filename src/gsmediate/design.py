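"""Two-stage Pocock group-sequential design mathematics.

A two-stage group-sequential design (GSD) compares two arms on a continuous
endpoint with one interim look.  The standardized test statistics
``(Z_1, Z_2)`` are jointly normal with ``Z_k ~ N(theta * sqrt(I_k), 1)`` and
``corr(Z_1, Z_2) = sqrt(I_1 / I_2)``, where ``I_k = n_k / (2 sigma^2)`` is the
information at stage k for a two-arm mean comparison with cumulative per-arm
sample size ``n_k``.  The Pocock rule applies the same critical value ``b`` at
both looks; ``b`` is chosen so that the overall two-sided type-I error equals
``alpha``.

All probabilities are computed by deterministic quadrature: the bivariate
normal rectangle probability is reduced to a one-dimensional integral over the
stage-one statistic and evaluated with adaptive Gauss-Kronrod quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize
from scipy.stats import norm

__all__ = [
    "GSDesign",
    "PowerDecomposition",
    "pocock_boundary",
    "gsd_power",
    "required_sample_size",
    "inflation_factor",
    "mc_prediction_interval",
]

#: z-quantile used throughout for 95% two-sided intervals.
_Z975 = 1.959964

_QUAD_EPS = 1e-10


@dataclass(frozen=True)
class GSDesign:
    """A fully resolved two-stage design.

    Parameters
    ----------
    alpha : float
        Two-sided type-I error rate, in (0, 1).
    info_fraction : float
        Fraction of the maximum information available at the interim look,
        in (0, 1).  The designs studied here use 0.5.
    boundary : float
        Pocock critical value applied at both stages.
    n_max_per_arm : int
        Maximum (stage-two cumulative) per-arm sample size.
    n_stage1_per_arm : int
        Per-arm sample size analysed at the interim.
    target_power : float
        Nominal power the design was sized for.
    design_delta : float
        Standardized effect size (mean difference / total SD of the outcome)
        the design was sized for.
    n_stages : int
        Number of analyses; fixed at 2.
    """

    alpha: float
    info_fraction: float
    boundary: float
    n_max_per_arm: int
    n_stage1_per_arm: int
    target_power: float = 0.9
    design_delta: float = float("nan")
    n_stages: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0.0 < self.info_fraction < 1.0):
            raise ValueError(
                f"info_fraction must be in (0, 1), got {self.info_fraction}"
            )
        if not self.boundary > 0.0:
            raise ValueError("boundary must be positive")
        if self.n_stages != 2:
            raise ValueError("only two-stage designs are supported")
        n1, n2 = self.n_stage1_per_arm, self.n_max_per_arm
        if not (isinstance(n1, (int, np.integer)) and isinstance(n2, (int, np.integer))):
            raise ValueError("per-arm sample sizes must be integers")
        if not (0 < n1 < n2):
            raise ValueError(
                f"need 0 < n_stage1_per_arm < n_max_per_arm, got {n1}, {n2}"
            )


@dataclass(frozen=True)
class PowerDecomposition:
    """Stage-wise decomposition of the rejection probability.

    ``overall = p_stop1 + p_reject2``: crossing at the interim and crossing at
    the final analysis after continuing are disjoint events.
    """

    p_stop1: float
    p_reject2: float
    overall: float

    def __post_init__(self) -> None:
        for name in ("p_stop1", "p_reject2", "overall"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{name}={v} outside [0, 1]")


def _bvn_rectangle(b: float, corr: float, mu1: float = 0.0, mu2: float = 0.0) -> float:
    """P(-b < Z1 < b, -b < Z2 < b) for a bivariate normal.

    (Z1, Z2) has means (mu1, mu2), unit variances and correlation ``corr``.
    Computed as an integral over z1 of the conditional normal probability;
    adaptive quadrature keeps the absolute error below 1e-10.
    """
    if not np.isfinite(b) or b <= 0:
        raise ValueError("rectangle half-width must be positive and finite")
    s = math.sqrt(1.0 - corr * corr)

    def integrand(z1: float) -> float:
        cond_mean = mu2 + corr * (z1 - mu1)
        return norm.pdf(z1, loc=mu1) * (
            norm.cdf((b - cond_mean) / s) - norm.cdf((-b - cond_mean) / s)
        )

    val, _ = integrate.quad(
        integrand, -b, b, epsabs=_QUAD_EPS, epsrel=_QUAD_EPS, limit=200
    )
    return float(val)


def _two_stage_rejection(
    b: float, corr: float, mu1: float = 0.0, mu2: float = 0.0
) -> tuple[float, float]:
    """(p_stop1, p_reject2) for symmetric boundary ``b`` at both stages."""
    p_stop1 = norm.cdf(-b - mu1) + norm.sf(b - mu1)
    p_in1 = 1.0 - p_stop1
    p_reject2 = p_in1 - _bvn_rectangle(b, corr, mu1, mu2)
    return float(p_stop1), float(max(p_reject2, 0.0))


def pocock_boundary(alpha: float, info_fraction: float) -> float:
    """Pocock critical value for a two-stage two-sided design.

    Solves ``P0(|Z1| >= b) + P0(|Z1| < b, |Z2| >= b) = alpha`` for ``b``,
    where ``(Z1, Z2)`` is standard bivariate normal with correlation
    ``sqrt(info_fraction)``.

    Examples
    --------
    >>> round(pocock_boundary(0.05, 0.5), 4)
    2.1783
    """
    if not (np.isfinite(alpha) and 0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be a finite number in (0, 1), got {alpha}")
    if not (np.isfinite(info_fraction) and 0.0 < info_fraction < 1.0):
        raise ValueError(f"info_fraction must be in (0, 1), got {info_fraction}")
    corr = math.sqrt(info_fraction)

    def err(b: float) -> float:
        p1, p2 = _two_stage_rejection(b, corr)
        return p1 + p2 - alpha

    lo, hi = 1.5, 4.0
    # Pocock two-stage with alpha in [0.01, 0.1] lies inside [1.5, 4];
    # widen adaptively otherwise.
    while err(lo) < 0.0 and lo > 1e-3:
        lo /= 2.0
    while err(hi) > 0.0 and hi < 64.0:
        hi *= 2.0
    if err(lo) < 0.0 or err(hi) > 0.0:
        raise ValueError(f"could not bracket a boundary for alpha={alpha}")
    return float(optimize.brentq(err, lo, hi, xtol=1e-10, maxiter=200))


def _power_continuous(
    delta: float, n_per_arm: float, info_fraction: float, boundary: float
) -> tuple[float, float]:
    """Stage-wise rejection probabilities at real-valued per-arm n."""
    n1 = info_fraction * n_per_arm
    mu1 = delta * math.sqrt(n1 / 2.0)
    mu2 = delta * math.sqrt(n_per_arm / 2.0)
    return _two_stage_rejection(boundary, math.sqrt(info_fraction), mu1, mu2)


def gsd_power(delta: float, design: GSDesign) -> PowerDecomposition:
    """Exact (quadrature-based) power of a two-stage design.

    ``Z_k ~ N(delta * sqrt(n_k / 2), 1)`` with ``n_k`` the cumulative per-arm
    sample size at stage k and ``corr(Z1, Z2) = sqrt(n_1 / n_2)``.
    """
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    n1, n2 = design.n_stage1_per_arm, design.n_max_per_arm
    mu1 = delta * math.sqrt(n1 / 2.0)
    mu2 = delta * math.sqrt(n2 / 2.0)
    p1, p2 = _two_stage_rejection(design.boundary, math.sqrt(n1 / n2), mu1, mu2)
    return PowerDecomposition(p_stop1=p1, p_reject2=p2, overall=p1 + p2)


def fixed_design_n(delta: float, alpha: float, power: float) -> float:
    """Continuous per-arm sample size of the fixed (single-look) design,
    ``2 (z_{1-alpha/2} + z_{power})^2 / delta^2``."""
    if delta == 0.0:
        raise ValueError("cannot size a design for a null effect")
    z_a = norm.ppf(1.0 - alpha / 2.0)
    z_b = norm.ppf(power)
    return 2.0 * (z_a + z_b) ** 2 / delta**2


def _gsd_n_continuous(
    delta: float, alpha: float, power: float, info_fraction: float, boundary: float
) -> float:
    """Real-valued per-arm n at which the GSD reaches the target power."""
    nf = fixed_design_n(delta, alpha, power)

    def gap(n: float) -> float:
        p1, p2 = _power_continuous(delta, n, info_fraction, boundary)
        return p1 + p2 - power

    lo, hi = 0.5 * nf, 2.0 * nf
    return float(optimize.brentq(gap, lo, hi, xtol=1e-8))


def required_sample_size(
    delta: float, alpha: float, power: float, info_fraction: float
) -> int:
    """Smallest integer per-arm maximum n reaching the target overall power.

    The boundary is computed once from (alpha, info_fraction); the power at a
    candidate n is evaluated with the interim at ``info_fraction * n``
    (real-valued, so the answer does not depend on how a non-integer interim
    count is rounded).

    Examples
    --------
    >>> required_sample_size(0.3481, 0.05, 0.90, 0.5)
    191
    """
    if delta == 0.0:
        raise ValueError("delta=0: effect is not detectable at any sample size")
    if not (alpha < power < 1.0):
        raise ValueError(f"power must lie in (alpha, 1), got {power}")
    b = pocock_boundary(alpha, info_fraction)
    delta = abs(delta)

    def overall(n: float) -> float:
        p1, p2 = _power_continuous(delta, n, info_fraction, b)
        return p1 + p2

    nf = fixed_design_n(delta, alpha, power)
    lo = max(2, math.floor(nf))  # GSD never needs fewer subjects than fixed
    hi = max(lo + 1, math.ceil(2.0 * nf))
    while overall(lo) >= power and lo > 2:
        lo = max(2, lo // 2)
    if overall(hi) < power:
        raise ValueError("no feasible sample size below twice the fixed design")
    # bisect on integers: overall(n) is increasing in n
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if overall(mid) >= power:
            hi = mid
        else:
            lo = mid
    return int(hi)


def inflation_factor(alpha: float, power: float, info_fraction: float) -> float:
    """Ratio of the (continuous) GSD per-arm sample size to the fixed-design
    one.  The effect size cancels, so the ratio is evaluated at an arbitrary
    delta; it exceeds 1 for every Pocock two-stage design."""
    b = pocock_boundary(alpha, info_fraction)
    delta = 0.3  # arbitrary; the ratio is delta-invariant
    n_gsd = _gsd_n_continuous(delta, alpha, power, info_fraction, b)
    return n_gsd / fixed_design_n(delta, alpha, power)


def mc_prediction_interval(p: float, n_reps: int) -> tuple[float, float]:
    """95% prediction interval for a simulated proportion.

    ``p -/+ 1.959964 * sqrt(p (1 - p) / n_reps)``, rounded to 4 decimals for
    reporting.

    Examples
    --------
    >>> mc_prediction_interval(0.05, 10000)
    (0.0457, 0.0543)
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    half = _Z975 * math.sqrt(p * (1.0 - p) / n_reps)
    return (round(p - half, 4), round(p + half, 4))


def make_design(
    alpha: float = 0.05,
    power: float = 0.9,
    delta: float = 0.3481,
    info_fraction: float = 0.5,
    n_max_per_arm: int | None = None,
) -> GSDesign:
    """Resolve a full :class:`GSDesign` from its inputs.

    If ``n_max_per_arm`` is not given it is computed from the effect size.
    The interim per-arm count is ``ceil(info_fraction * n)`` when the exact
    fraction is not an integer.
    """
    b = pocock_boundary(alpha, info_fraction)
    if n_max_per_arm is None:
        n_max_per_arm = required_sample_size(delta, alpha, power, info_fraction)
    n1 = math.ceil(info_fraction * n_max_per_arm)
    return GSDesign(
        alpha=alpha,
        info_fraction=info_fraction,
        boundary=b,
        n_max_per_arm=int(n_max_per_arm),
        n_stage1_per_arm=int(n1),
        target_power=power,
        design_delta=delta,
    )
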
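"""Triangular stopping boundaries, FWER calibration, and sample-size search.

The triangular boundary family (for equally spaced analyses) is

    u_j = C (1 + j/J) / sqrt(j),      l_j = C (-1 + 3 j/J) / sqrt(j),

so the efficacy and futility limits converge at the final analysis
(``u_J = l_J = 2 C / sqrt(J)``).  The scale constant ``C`` is calibrated by
root finding so that the familywise error rate of the pre-change trial —
the probability, under the global null, that any experimental arm ever
crosses the upper boundary before being dropped for futility — equals the
nominal one-sided level.  Pairwise power is the marginal probability that a
single arm with a given true effect crosses the upper boundary at some
analysis of its two-arm comparison against the control; the per-stage
sample size is the smallest integer meeting the nominal pairwise power.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .design_model import DesignSpec
from .joint_gaussian import (
    StatisticRef,
    covariance,
    mvn_rectangle_prob,
)

__all__ = [
    "BoundaryShape",
    "triangular_boundaries",
    "familywise_error",
    "calibrate_constant",
    "ensure_boundaries",
    "pairwise_power",
    "required_sample_size",
]

_CALIBRATION_QMC_POINTS = 1 << 14


@dataclass(frozen=True)
class BoundaryShape:
    """A boundary family and its scale constant."""

    name: str
    C: float

    def __post_init__(self) -> None:
        if self.name != "triangular":
            raise ValueError(f"unknown boundary shape {self.name!r}")
        if not self.C > 0:
            raise ValueError(f"shape constant must be positive, got {self.C}")

    def boundaries(self, J: int) -> tuple[tuple[float, ...], tuple[float, ...]]:
        return triangular_boundaries(self.C, J)


def triangular_boundaries(C: float, J: int) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Upper and lower triangular boundaries for ``J`` equally spaced analyses."""
    if not C > 0:
        raise ValueError(f"C must be positive, got {C}")
    if not (int(J) == J and J >= 1):
        raise ValueError(f"J must be an integer >= 1, got {J}")
    j = np.arange(1, J + 1, dtype=float)
    upper = C * (1.0 + j / J) / np.sqrt(j)
    lower = C * (-1.0 + 3.0 * j / J) / np.sqrt(j)
    return tuple(upper), tuple(lower)


def _no_reject_pieces(design: DesignSpec) -> list[list[tuple[float, float]]]:
    """Disjoint per-arm paths that never cross the upper boundary.

    A path either drops for futility at stage ``s < J`` (in-range before,
    below ``l_s`` at ``s``) or reaches the final analysis without rejection.
    Each piece is a list of per-stage (lower, upper) bounds padded with
    (-inf, inf) for stages after the arm has stopped.
    """
    J, u, l = design.J, design.upper, design.lower
    pieces = []
    for s in range(1, J):
        bounds = [(l[t - 1], u[t - 1]) for t in range(1, s)]
        bounds.append((-np.inf, l[s - 1]))
        bounds += [(-np.inf, np.inf)] * (J - s)
        pieces.append(bounds)
    final = [(l[t - 1], u[t - 1]) for t in range(1, J)] + [(-np.inf, u[J - 1])]
    pieces.append(final)
    return pieces


def familywise_error(
    design: DesignSpec,
    *,
    futility: str = "nonbinding",
    n_points: int = _CALIBRATION_QMC_POINTS,
) -> float:
    """One-sided FWER of the pre-change trial at the global null.

    With ``futility="nonbinding"`` (the boundary-calibration convention: the
    error guarantee must survive even if futility stopping is overrun) this
    is one minus the probability that every statistic stays at or below its
    upper boundary at every analysis.  With ``futility="binding"`` an arm
    that falls below ``l_j`` can no longer reject, and the rejection-free
    event is expanded as a disjoint union of per-arm stopping paths.
    """
    if not design.has_boundaries:
        raise ValueError("design has no boundaries; calibrate first")
    K, J = design.K, design.J
    if K * J > 12:
        raise ValueError(
            f"joint dimension {K * J} exceeds the rectangle-probability cap; "
            "use the trial simulator estimate instead"
        )
    refs = [StatisticRef("pre", k=k, j=j) for k in range(1, K + 1) for j in range(1, J + 1)]
    cov = covariance(refs, design)
    if futility == "nonbinding":
        lo = np.full(K * J, -np.inf)
        hi = np.array([design.upper[r.j - 1] for r in refs])
        no_reject = mvn_rectangle_prob(lo, hi, np.zeros(K * J), cov, n_points=n_points)
        return float(1.0 - no_reject)
    if futility != "binding":
        raise ValueError(f"futility must be 'binding' or 'nonbinding', got {futility!r}")
    pieces = _no_reject_pieces(design)
    combos = list(itertools.product(pieces, repeat=K))
    lo = np.array([[b[0] for arm in combo for b in arm] for combo in combos])
    hi = np.array([[b[1] for arm in combo for b in arm] for combo in combos])
    probs = mvn_rectangle_prob(lo, hi, np.zeros(K * J), cov, n_points=n_points)
    return float(1.0 - np.sum(probs))


def calibrate_constant(
    K: int,
    J: int,
    alpha_fwer: float,
    *,
    n_per_stage: int = 1,
    sigma: float = 1.0,
    bracket: tuple[float, float] = (0.2, 5.0),
    futility: str = "nonbinding",
) -> BoundaryShape:
    """Find the triangular constant ``C`` with FWER equal to ``alpha_fwer``.

    The FWER at the global null does not depend on ``n_per_stage`` or
    ``sigma`` (the statistics are pivotal), so calibration precedes the
    sample-size search.
    """
    if not (0.0 < alpha_fwer < 1.0):
        raise ValueError(f"alpha_fwer must lie in (0, 1), got {alpha_fwer}")

    def gap(C: float) -> float:
        upper, lower = triangular_boundaries(C, J)
        d = DesignSpec(K=K, J=J, n_per_stage=n_per_stage, sigma=sigma,
                       upper=upper, lower=lower, alpha_fwer=alpha_fwer)
        return familywise_error(d, futility=futility) - alpha_fwer

    g_lo, g_hi = gap(bracket[0]), gap(bracket[1])
    if not (g_lo > 0 > g_hi):
        raise ValueError(
            f"bracket {bracket} does not straddle the root "
            f"(gap values {g_lo:.3g}, {g_hi:.3g}); widen the bracket"
        )
    C = brentq(gap, *bracket, xtol=1e-9, rtol=1e-12)
    return BoundaryShape(name="triangular", C=float(C))


def ensure_boundaries(design: DesignSpec) -> DesignSpec:
    """Return a design with boundaries, calibrating the shape if needed."""
    if design.has_boundaries:
        return design
    shape = calibrate_constant(design.K, design.J, design.alpha_fwer,
                               n_per_stage=design.n_per_stage, sigma=design.sigma)
    upper, lower = shape.boundaries(design.J)
    return design.with_boundaries(upper, lower)


def pairwise_power(
    n_per_stage: int,
    design: DesignSpec,
    theta: float,
    *,
    n_points: int = _CALIBRATION_QMC_POINTS,
) -> float:
    """Probability one arm with true effect ``theta`` crosses the upper boundary.

    Sum over stopping stages ``j`` of
    ``P(l_s <= Z_s <= u_s for s < j, Z_j > u_j)`` for the two-arm
    group-sequential comparison, with drift ``theta * sqrt(n_j / (2 sigma^2))``.
    """
    if not design.has_boundaries:
        raise ValueError("design has no boundaries; calibrate first")
    if n_per_stage < 1:
        raise ValueError(f"n_per_stage must be >= 1, got {n_per_stage}")
    J, u, l = design.J, design.upper, design.lower
    j = np.arange(1, J + 1, dtype=float)
    mean = theta * np.sqrt(j * n_per_stage / (2.0 * design.sigma**2))
    refs = [StatisticRef("pre", k=1, j=int(jj)) for jj in j]
    probe = DesignSpec(K=design.K, J=J, n_per_stage=n_per_stage, sigma=design.sigma,
                       upper=u, lower=l, alpha_fwer=design.alpha_fwer)
    cov = covariance(refs, probe)
    lo = np.full((J, J), -np.inf)
    hi = np.full((J, J), np.inf)
    for stop in range(J):
        for s in range(stop):
            lo[stop, s], hi[stop, s] = l[s], u[s]
        lo[stop, stop] = u[stop]
    probs = mvn_rectangle_prob(lo, hi, mean, cov, n_points=n_points)
    return float(np.sum(probs))


def required_sample_size(
    design: DesignSpec,
    theta1: float | None = None,
    power_target: float | None = None,
) -> tuple[int, int]:
    """Smallest per-arm per-stage ``n`` with pairwise power at ``theta1``
    reaching ``power_target``; returns ``(n, total_max_N)``.

    Scans integers upward from an analytic two-arm fixed-design lower bound
    (a group-sequential design cannot beat the fixed test using its full
    final-stage information).
    """
    theta1 = design.theta1 if theta1 is None else theta1
    power_target = design.power_target if power_target is None else power_target
    if theta1 is None or power_target is None:
        raise ValueError("theta1 and power_target must be set on the design or passed")
    if not (0.0 < power_target < 1.0):
        raise ValueError(f"power_target must lie in (0, 1), got {power_target}")
    if not theta1 > 0:
        raise ValueError(f"theta1 must be positive, got {theta1}")
    if not design.has_boundaries:
        raise ValueError("design has no boundaries; calibrate first")

    # Fixed-design bound: total per-arm n with z-test power at the final
    # critical value u_J; the sequential test needs at least this much.
    z_beta = norm.ppf(power_target)
    n_total_fixed = 2.0 * design.sigma**2 * (design.upper[-1] + z_beta) ** 2 / theta1**2
    n = max(1, int(np.floor(n_total_fixed / design.J)))
    while pairwise_power(n, design, theta1) < power_target:
        n += 1
    while n > 1 and pairwise_power(n - 1, design, theta1) >= power_target:
        n -= 1
    return n, n * design.J * (design.K + 1)
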
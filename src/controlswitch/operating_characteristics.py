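"""Conditional power, conditional type-I error, and overall power.

The quantities are defined through four events, for a candidate arm
``k_star`` and a control change to arm ``k_prime`` at stage ``j_prime``:

* E1 — arm ``k_prime`` becomes the control at ``j_prime``: it stays between
  the boundaries up to ``j_prime - 1`` and crosses the upper boundary at
  ``j_prime``;
* E2 — arm ``k_star`` is still in the trial at the change: its statistic
  never fell below the lower boundary up to and including ``j_prime``;
* E3 — no other arm becomes the control: no other arm crosses the upper
  boundary before ``j_prime``, and any arm crossing at ``j_prime`` has a
  smaller statistic than arm ``k_prime`` (the largest-crosser tie rule);
* E4 — ``k_star`` is declared superior to the new control at some remaining
  analysis, using either the retained statistic ``Z[k_star, k_prime, j]``
  (all data) or the post-change-only statistic ``Z*`` (E4*).

Conditional power is ``P(E1 n E2 n E3 n E4) / P(E1 n E2 n E3)`` under the
retain policy and, by independence of the post-change increments, simply
``P(E4*)`` under the discard policy.  The conditional type-I error is the
same quantity evaluated on scenarios with ``mu_{k_star} <= mu_{k_prime}``.
Overall power for the arm with the greatest true effect decomposes into
``Xi`` terms (that arm becomes the control itself) and ``Omega`` terms
(another arm becomes control and the best arm later beats it).

Events are decomposed into disjoint unions of Gaussian rectangles; the
largest-crosser ordering is carried as order constraints against the
change-stage statistic of ``k_prime`` and resolved inside
:func:`controlswitch.joint_gaussian.region_probability` by conditioning on
that pivot.  By default an arm that crosses the upper boundary at the
change stage without having the largest statistic stays in the trial;
``crossers_remain_active=False`` switches to the stricter reading in which
any such arm would have left, i.e. the change-stage statistics of the
remaining arms are additionally bounded above by ``u_{j_prime}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design_model import ChangeConfig, DesignSpec, OCResult, Policy, ScenarioMeans
from .joint_gaussian import (
    DEFAULT_QMC_POINTS,
    DEFAULT_QUAD_NODES,
    EventRegion,
    StatisticRef,
    region_probability,
)

__all__ = [
    "EventSpec",
    "build_events",
    "conditional_power",
    "conditional_power_both",
    "conditional_type1",
    "overall_power",
    "overall_power_both",
    "becomes_control_probability",
    "wrong_control_probability",
    "ConditioningError",
]

_DENOM_FLOOR = 1e-12


class ConditioningError(ValueError):
    """The conditioning event has negligible probability."""


@dataclass(frozen=True)
class EventSpec:
    """A trial event expressed as a disjoint union of Gaussian regions."""

    kind: str
    k_star: int | None
    change: ChangeConfig
    regions: tuple[EventRegion, ...]

    def probability(self, design: DesignSpec, means: ScenarioMeans, **kw) -> float:
        return float(sum(region_probability(r, design, means, **kw) for r in self.regions))


def _stage_bounds(design: DesignSpec, j: int) -> tuple[float, float]:
    return design.lower[j - 1], design.upper[j - 1]


def _pre_path(design: DesignSpec, arm: int, upto: int) -> tuple[list, list, list]:
    """In-range path of ``arm`` through stages 1..upto-1: refs, lower, upper."""
    refs, lo, hi = [], [], []
    for s in range(1, upto):
        l, u = _stage_bounds(design, s)
        refs.append(StatisticRef("pre", k=arm, j=s))
        lo.append(l)
        hi.append(u)
    return refs, lo, hi


def _other_arm_pieces(design: DesignSpec, arm: int, j_prime: int,
                      crossers_remain_active: bool) -> list[tuple[list, list, list, bool]]:
    """Disjoint paths of a non-candidate arm compatible with E3.

    Either the arm drops for futility at some stage before the change, or it
    reaches the change stage, where its statistic must not beat the pivot
    (returned flag ``True`` marks the stage-``j_prime`` coordinate that
    carries the order constraint).
    """
    pieces = []
    for s in range(1, j_prime):  # dropped at stage s
        refs, lo, hi = _pre_path(design, arm, s)
        refs.append(StatisticRef("pre", k=arm, j=s))
        lo.append(-np.inf)
        hi.append(design.lower[s - 1])
        pieces.append((refs, lo, hi, False))
    refs, lo, hi = _pre_path(design, arm, j_prime)  # survives to the change stage
    refs.append(StatisticRef("pre", k=arm, j=j_prime))
    lo.append(-np.inf)
    hi.append(design.upper[j_prime - 1] if not crossers_remain_active else np.inf)
    pieces.append((refs, lo, hi, crossers_remain_active))
    return pieces


def _conditioning_regions(
    design: DesignSpec,
    k_prime: int,
    j_prime: int,
    k_star: int | None,
    *,
    crossers_remain_active: bool = True,
) -> list[EventRegion]:
    """Disjoint regions of E1 n E3 (n E2 when ``k_star`` is given)."""
    if not design.has_boundaries:
        raise ValueError("design has no boundaries; calibrate first")
    # E1: the new control's path, pivot last among its coordinates.
    refs, lo, hi = _pre_path(design, k_prime, j_prime)
    refs.append(StatisticRef("pre", k=k_prime, j=j_prime))
    lo.append(design.upper[j_prime - 1])
    hi.append(np.inf)
    pivot = len(refs) - 1

    constraints: list[tuple[int, int]] = []
    if k_star is not None and k_star != k_prime:
        # E2: k_star in range before the change and above l at the change.
        r2, l2, h2 = _pre_path(design, k_star, j_prime)
        refs += r2
        lo += l2
        hi += h2
        refs.append(StatisticRef("pre", k=k_star, j=j_prime))
        lo.append(design.lower[j_prime - 1])
        hi.append(design.upper[j_prime - 1] if not crossers_remain_active else np.inf)
        if crossers_remain_active:
            constraints.append((pivot, len(refs) - 1))

    others = [a for a in range(1, design.K + 1)
              if a != k_prime and (k_star is None or a != k_star)]
    regions: list[EventRegion] = []

    def expand(i: int, refs_acc, lo_acc, hi_acc, con_acc) -> None:
        if i == len(others):
            regions.append(EventRegion(tuple(refs_acc), tuple(lo_acc), tuple(hi_acc),
                                       tuple(con_acc)))
            return
        for prefs, plo, phi, ordered in _other_arm_pieces(
            design, others[i], j_prime, crossers_remain_active
        ):
            n0 = len(refs_acc)
            new_con = list(con_acc)
            if ordered:
                new_con.append((pivot, n0 + len(prefs) - 1))
            expand(i + 1, refs_acc + prefs, lo_acc + plo, hi_acc + phi, new_con)

    expand(0, refs, lo, hi, constraints)
    return regions


def _rejection_pieces(design: DesignSpec, k_star: int, k_prime: int, j_prime: int,
                      kind: str) -> list[EventRegion]:
    """Disjoint first-crossing paths of the post-change comparison (E4/E4*)."""
    regions = []
    for stop in range(j_prime + 1, design.J + 1):
        refs, lo, hi = [], [], []
        for s in range(j_prime + 1, stop + 1):
            if kind == "E4":
                refs.append(StatisticRef("retained", k=k_star, j=s, comparator=k_prime))
            else:
                refs.append(StatisticRef("post_only", k=k_star, j=s, comparator=k_prime,
                                         j_prime=j_prime))
            if s < stop:
                l, u = _stage_bounds(design, s)
                lo.append(l)
                hi.append(u)
            else:
                lo.append(design.upper[s - 1])
                hi.append(np.inf)
        regions.append(EventRegion(tuple(refs), tuple(lo), tuple(hi)))
    return regions


def _combine(pre: EventRegion, post: EventRegion) -> EventRegion:
    return EventRegion(
        pre.refs + post.refs,
        pre.lower + post.lower,
        pre.upper + post.upper,
        pre.order_constraints,  # post coordinates never enter the tie rule
    )


def build_events(
    design: DesignSpec,
    change: ChangeConfig,
    k_star: int,
    *,
    crossers_remain_active: bool = True,
) -> dict[str, EventSpec]:
    """Regions for E1, E2, E3, E4 and E4*, plus the composites the
    calculations use (``E123``: conditioning event; ``E1234``: retain-policy
    rejection event).

    Standalone E2/E3 regions include the change-stage pivot statistic of
    ``k_prime`` (unbounded) because the tie rule is an ordering against it.
    """
    change.validate_for(design)
    if k_star == change.k_prime:
        raise ValueError("k_star must differ from k_prime")
    if not (1 <= k_star <= design.K):
        raise ValueError(f"k_star={k_star} outside 1..{design.K}")
    kp, jp = change.k_prime, change.j_prime

    refs, lo, hi = _pre_path(design, kp, jp)
    refs.append(StatisticRef("pre", k=kp, j=jp))
    lo.append(design.upper[jp - 1])
    hi.append(np.inf)
    e1 = [EventRegion(tuple(refs), tuple(lo), tuple(hi))]

    pivot_ref = StatisticRef("pre", k=kp, j=jp)

    r2, l2, h2 = _pre_path(design, k_star, jp)
    r2.append(StatisticRef("pre", k=k_star, j=jp))
    l2.append(design.lower[jp - 1])
    h2.append(design.upper[jp - 1] if not crossers_remain_active else np.inf)
    con2 = ()
    if crossers_remain_active:
        r2 = [pivot_ref] + r2
        l2 = [-np.inf] + l2
        h2 = [np.inf] + h2
        con2 = ((0, len(r2) - 1),)
    e2 = [EventRegion(tuple(r2), tuple(l2), tuple(h2), con2)]

    e3 = []
    others = [a for a in range(1, design.K + 1) if a not in (kp, k_star)]
    for arm in others:
        for prefs, plo, phi, ordered in _other_arm_pieces(design, arm, jp, crossers_remain_active):
            if ordered:
                prefs, plo, phi = [pivot_ref] + prefs, [-np.inf] + plo, [np.inf] + phi
                con = ((0, len(prefs) - 1),)
            else:
                con = ()
            e3.append(EventRegion(tuple(prefs), tuple(plo), tuple(phi), con))

    cond = _conditioning_regions(design, kp, jp, k_star,
                                 crossers_remain_active=crossers_remain_active)
    e4 = _rejection_pieces(design, k_star, kp, jp, "E4")
    e4s = _rejection_pieces(design, k_star, kp, jp, "E4_star")
    e1234 = [_combine(p, q) for p in cond for q in e4]

    out = {
        "E1": e1, "E2": e2, "E3": e3, "E4": e4, "E4_star": e4s,
        "E123": cond, "E1234": e1234,
    }
    return {k: EventSpec(k, k_star, change, tuple(v)) for k, v in out.items()}


def conditional_power_both(
    design: DesignSpec,
    means: ScenarioMeans,
    change: ChangeConfig,
    k_star: int,
    *,
    crossers_remain_active: bool = True,
    n_points: int = DEFAULT_QMC_POINTS,
    n_nodes: int = DEFAULT_QUAD_NODES,
) -> tuple[float, float]:
    """Conditional power under both policies, sharing the conditioning event.

    Returns ``(retain, discard)``.
    """
    change.validate_for(design)
    if k_star == change.k_prime:
        raise ValueError("k_star must differ from k_prime")
    kw = dict(n_points=n_points, n_nodes=n_nodes)
    kp, jp = change.k_prime, change.j_prime
    cond = _conditioning_regions(design, kp, jp, k_star,
                                 crossers_remain_active=crossers_remain_active)
    den = sum(region_probability(r, design, means, **kw) for r in cond)
    if den < _DENOM_FLOOR:
        raise ConditioningError(
            f"conditioning event has negligible probability ({den:.3g})"
        )
    e4 = _rejection_pieces(design, k_star, kp, jp, "E4")
    num = sum(region_probability(_combine(p, q), design, means, **kw)
              for p in cond for q in e4)
    retain = float(min(1.0, max(0.0, num / den)))
    e4s = _rejection_pieces(design, k_star, kp, jp, "E4_star")
    discard = float(min(1.0, sum(region_probability(r, design, means, **kw) for r in e4s)))
    return retain, discard


def conditional_power(
    design: DesignSpec,
    means: ScenarioMeans,
    change: ChangeConfig,
    k_star: int,
    **kw,
) -> float:
    """Probability that ``k_star`` beats the new control by the final analysis.

    Retain policy: ratio of the joint event probability to the conditioning
    probability.  Discard policy: the post-change-only statistics are
    independent of everything observed before the change, so the value is
    the unconditional first-crossing probability of ``Z*``.
    """
    retain, discard = conditional_power_both(design, means, change, k_star, **kw)
    return retain if change.policy == "retain" else discard


def conditional_type1(
    design: DesignSpec,
    means: ScenarioMeans,
    change: ChangeConfig,
    k_star: int,
    **kw,
) -> float | None:
    """Conditional probability of wrongly declaring ``k_star`` superior.

    Defined only when ``mu_{k_star} <= mu_{k_prime}``; returns ``None``
    otherwise (no type-I error can be made).
    """
    if means.mu[k_star] > means.mu[change.k_prime]:
        return None
    return conditional_power(design, means, change, k_star, **kw)


def becomes_control_probability(
    design: DesignSpec,
    means: ScenarioMeans,
    arm: int,
    j_star: int,
    *,
    crossers_remain_active: bool = True,
    n_points: int = DEFAULT_QMC_POINTS,
    n_nodes: int = DEFAULT_QUAD_NODES,
) -> float:
    """Xi term: probability ``arm`` becomes the control at stage ``j_star``."""
    if not (1 <= j_star <= design.J):
        raise ValueError(f"j_star={j_star} outside 1..{design.J}")
    regions = _conditioning_regions(design, arm, j_star, None,
                                    crossers_remain_active=crossers_remain_active)
    kw = dict(n_points=n_points, n_nodes=n_nodes)
    return float(sum(region_probability(r, design, means, **kw) for r in regions))


def wrong_control_probability(
    design: DesignSpec,
    means: ScenarioMeans,
    k_star: int | None = None,
    *,
    j_star: int = 1,
    **kw,
) -> float:
    """Probability an arm other than the best one becomes control at ``j_star``."""
    if k_star is None:
        k_star = _best_arm(means)
    return float(sum(becomes_control_probability(design, means, arm, j_star, **kw)
                     for arm in range(1, design.K + 1) if arm != k_star))


def _best_arm(means: ScenarioMeans) -> int:
    effects = list(means.mu[1:])
    best = max(effects)
    winners = [i + 1 for i, e in enumerate(effects) if e == best]
    if len(winners) > 1:
        raise ValueError(
            f"arms {winners} tie for the greatest effect; pass k_star explicitly"
        )
    return winners[0]


def overall_power_both(
    design: DesignSpec,
    means: ScenarioMeans,
    k_star: int | None = None,
    *,
    crossers_remain_active: bool = True,
    n_points: int = DEFAULT_QMC_POINTS,
    n_nodes: int = DEFAULT_QUAD_NODES,
) -> dict[Policy, OCResult]:
    """Overall power under both policies, sharing the policy-free components.

    The Xi terms and the conditioning probabilities do not depend on the
    data policy; only the post-change rejection event differs.
    """
    if k_star is None:
        k_star = _best_arm(means)
    if not (1 <= k_star <= design.K):
        raise ValueError(f"k_star={k_star} outside 1..{design.K}")
    kw = dict(n_points=n_points, n_nodes=n_nodes)

    xi = tuple(
        becomes_control_probability(design, means, k_star, j, n_points=n_points,
                                    n_nodes=n_nodes,
                                    crossers_remain_active=crossers_remain_active)
        for j in range(1, design.J + 1)
    )

    omega_r: dict[tuple[int, int], float] = {}
    omega_d: dict[tuple[int, int], float] = {}
    for kp in range(1, design.K + 1):
        if kp == k_star:
            continue
        for jp in range(1, design.J + 1):
            if jp == design.J:
                omega_r[(kp, jp)] = omega_d[(kp, jp)] = 0.0
                continue
            cond = _conditioning_regions(design, kp, jp, k_star,
                                         crossers_remain_active=crossers_remain_active)
            e4 = _rejection_pieces(design, k_star, kp, jp, "E4")
            omega_r[(kp, jp)] = float(
                sum(region_probability(_combine(p, q), design, means, **kw)
                    for p in cond for q in e4)
            )
            pre = sum(region_probability(r, design, means, **kw) for r in cond)
            e4s = _rejection_pieces(design, k_star, kp, jp, "E4_star")
            rej = sum(region_probability(r, design, means, **kw) for r in e4s)
            omega_d[(kp, jp)] = float(pre * rej)

    out: dict[Policy, OCResult] = {}
    for policy, omega in (("retain", omega_r), ("discard", omega_d)):
        result = OCResult(
            policy=policy,
            scenario=means,
            overall_power=float(sum(xi) + sum(omega.values())),
            xi_terms=xi,
            omega_terms=omega,
        )
        result.check(tol=1e-6)
        out[policy] = result
    return out


def overall_power(
    design: DesignSpec,
    means: ScenarioMeans,
    policy: Policy,
    k_star: int | None = None,
    **kw,
) -> OCResult:
    """Probability the best arm is found: it becomes the control at some
    stage (Xi terms) or another arm does and the best arm later beats it
    (Omega terms; under the discard policy the rejection factorises off).

    Omega terms for a change at the final analysis are zero by construction
    (no analysis remains at which the best arm could beat the new control);
    they are reported as exact zeros rather than omitted.
    """
    if policy not in ("retain", "discard"):
        raise ValueError(f"policy must be 'retain' or 'discard', got {policy!r}")
    return overall_power_both(design, means, k_star, **kw)[policy]
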
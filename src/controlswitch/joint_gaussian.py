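"""Exact joint Gaussian law of pre- and post-change test statistics.

Every test statistic in the trial is a linear combination of independent
per-arm, per-stage response-sum increments ``D[k, t] = S[k, t] - S[k, t-1]``
(``S[k, t]`` the cumulative response sum of arm ``k`` at analysis ``t``),
with ``D[k, t] ~ N(n * mu_k, n * sigma^2)`` and ``n = n_per_stage``:

* pre-change      ``Z[k, 0, j]       = (S[k, j] - S[0, j]) / (sigma * sqrt(2 n_j))``
* retained        ``Z[k, k', j]      = (S[k, j] - S[k', j]) / (sigma * sqrt(2 n_j))``
* post-change-only``Z*[k, k', j, j'] = (S[k, j] - S[k, j'] - S[k', j] + S[k', j'])
  / (sigma * sqrt(2 (n_j - n_j')))``

Writing each statistic as a coefficient vector over the increments makes
every mean (drift) and covariance an exact inner product, valid for any
mixture of statistic kinds, and yields covariance matrices that are
positive semi-definite by construction (Gram matrices).

Rectangle probabilities under these laws are computed by a batched
Genz-style sequential-conditioning quasi-Monte Carlo routine driven by a
fixed-seed scrambled Sobol sequence, so results are deterministic.  Regions
carrying order constraints of the form ``ref_a >= ref_b`` (the
largest-statistic tie rule at the control change) are reduced to plain
rectangles by conditioning on the shared pivot statistic with
Gauss-Legendre quadrature; the conditional law of a Gaussian vector given
one coordinate is again Gaussian with a value-independent covariance, so
the inner integrand is a batch of rectangles sharing one Cholesky factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import qmc

from .design_model import DesignSpec, ScenarioMeans

__all__ = [
    "StatisticRef",
    "EventRegion",
    "drift",
    "covariance",
    "region_probability",
    "mvn_rectangle_prob",
    "QMC_SEED",
    "DEFAULT_QMC_POINTS",
    "DEFAULT_QUAD_NODES",
    "DIM_CAP",
]

# Fixed quasi-Monte Carlo scramble seed: part of the numerical contract so
# that identical inputs give bit-identical probabilities.
QMC_SEED = 20230545
DEFAULT_QMC_POINTS = 1 << 13
DEFAULT_QUAD_NODES = 48
DIM_CAP = 12
_TAIL = 8.5  # standardised integration cut-off; N(0,1) mass beyond is < 1e-17


@dataclass(frozen=True)
class StatisticRef:
    """Reference to one test statistic of the trial.

    kind:
        ``pre``       — Z[k, 0, j], experimental arm vs the original control;
        ``retained``  — Z[k, k', j], all data, vs the new control k';
        ``post_only`` — Z*[k, k', j, j'], post-change data only.
    """

    kind: Literal["pre", "retained", "post_only"]
    k: int
    j: int
    comparator: int = 0
    j_prime: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "pre":
            if self.comparator != 0:
                raise ValueError("pre-change statistics compare against arm 0")
        elif self.kind in ("retained", "post_only"):
            if self.comparator == self.k:
                raise ValueError("statistic compares an arm with itself")
            if self.kind == "post_only":
                if self.j_prime is None or self.j <= self.j_prime:
                    raise ValueError("post_only requires j > j_prime")
        else:
            raise ValueError(f"unknown statistic kind {self.kind!r}")

    def validate_for(self, design: DesignSpec) -> None:
        if not (1 <= self.j <= design.J):
            raise ValueError(f"stage {self.j} outside 1..{design.J}")
        for arm in (self.k, self.comparator):
            if not (0 <= arm <= design.K):
                raise ValueError(f"arm {arm} outside 0..{design.K}")


def _coefficients(ref: StatisticRef, design: DesignSpec) -> np.ndarray:
    """Coefficient vector of ``ref`` over the (K+1) x J increment array."""
    ref.validate_for(design)
    n = design.n_per_stage
    c = np.zeros((design.K + 1, design.J))
    if ref.kind in ("pre", "retained"):
        scale = 1.0 / (design.sigma * np.sqrt(2.0 * n * ref.j))
        c[ref.k, : ref.j] = scale
        c[ref.comparator, : ref.j] = -scale
    else:  # post_only
        jp = ref.j_prime
        scale = 1.0 / (design.sigma * np.sqrt(2.0 * n * (ref.j - jp)))
        c[ref.k, jp: ref.j] = scale
        c[ref.comparator, jp: ref.j] = -scale
    return c.ravel()


def drift(ref: StatisticRef, design: DesignSpec, means: ScenarioMeans) -> float:
    """Mean of the statistic under the scenario.

    Equals ``(mu_k - mu_comparator) * sqrt(n_j / (2 sigma^2))`` for full-data
    statistics and ``(mu_k - mu_comparator) * sqrt((n_j - n_j') / (2 sigma^2))``
    for post-change-only statistics.
    """
    if means.K != design.K:
        raise ValueError("scenario arm count does not match design")
    c = _coefficients(ref, design).reshape(design.K + 1, design.J)
    incr_mean = design.n_per_stage * np.asarray(means.mu)
    return float(c.sum(axis=1) @ incr_mean)


def covariance(refs: Sequence[StatisticRef], design: DesignSpec) -> np.ndarray:
    """Exact covariance matrix of the referenced statistics (unit diagonal).

    Gram matrix of the increment-coefficient vectors scaled by the increment
    variance ``n * sigma^2``; positive semi-definite by construction.
    """
    C = np.array([_coefficients(r, design) for r in refs])
    cov = (design.n_per_stage * design.sigma**2) * (C @ C.T)
    eigmin = float(np.linalg.eigvalsh(cov).min()) if len(refs) else 0.0
    if eigmin < -1e-10:
        raise ValueError(f"covariance not PSD (min eigenvalue {eigmin})")
    return cov


@dataclass(frozen=True)
class EventRegion:
    """Rectangle, optionally with pairwise order constraints, on statistics.

    ``order_constraints`` holds index pairs ``(a, b)`` meaning
    ``refs[a] >= refs[b]``.
    """

    refs: tuple[StatisticRef, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    order_constraints: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        d = len(self.refs)
        if not (len(self.lower) == len(self.upper) == d):
            raise ValueError("bounds must match the number of statistics")
        for lo, hi in zip(self.lower, self.upper):
            if lo > hi:
                raise ValueError(f"inconsistent bounds: lower {lo} > upper {hi}")
        for a, b in self.order_constraints:
            if not (0 <= a < d and 0 <= b < d) or a == b:
                raise ValueError(f"order constraint ({a}, {b}) references invalid statistics")


def _cholesky(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        # Gram construction guarantees PSD; tolerate rounding at machine scale.
        jitter = 1e-12 * np.eye(cov.shape[0])
        try:
            return np.linalg.cholesky(cov + jitter)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "covariance is singular; the statistic set is linearly dependent"
            ) from exc


@lru_cache(maxsize=32)
def _sobol(dim: int, n_points: int) -> np.ndarray:
    sampler = qmc.Sobol(d=dim, scramble=True, rng=np.random.default_rng(QMC_SEED))
    return sampler.random(n_points)


@lru_cache(maxsize=8)
def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


_EPS = 1e-15


def mvn_rectangle_prob(
    lower: np.ndarray,
    upper: np.ndarray,
    mean: np.ndarray,
    cov: np.ndarray,
    *,
    n_points: int = DEFAULT_QMC_POINTS,
) -> np.ndarray | float:
    """P(lower <= X <= upper) for X ~ N(mean, cov), batched over bound sets.

    ``lower``/``upper``/``mean`` broadcast to shape ``(R, d)`` with a single
    shared ``cov``; returns shape ``(R,)`` (or a scalar for 1-D input).  Uses
    the Genz sequential-conditioning transformation with a fixed scrambled
    Sobol point set, vectorised over both the batch and the QMC points.
    """
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    d = cov.shape[0]
    lower, upper, mean = np.atleast_1d(lower, upper, mean)
    scalar_in = lower.ndim == 1 and upper.ndim == 1 and mean.ndim == 1
    lo = np.atleast_2d(lower) - np.atleast_2d(mean)
    hi = np.atleast_2d(upper) - np.atleast_2d(mean)
    lo, hi = np.broadcast_arrays(lo, hi)
    lo = lo.astype(float)
    hi = hi.astype(float)
    if lo.shape[1] != d:
        raise ValueError("bounds dimension does not match covariance")

    if d == 1:
        s = np.sqrt(cov[0, 0])
        out = ndtr(hi[:, 0] / s) - ndtr(lo[:, 0] / s)
        out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if scalar_in else out

    L = _cholesky(cov)
    R = lo.shape[0]
    w = _sobol(d - 1, n_points)  # (M, d-1)
    M = n_points

    # Sequential conditioning: coordinates of the standardised sample.
    y = np.empty((R, M, d - 1))
    d0 = ndtr(lo[:, 0] / L[0, 0])[:, None]  # (R, 1)
    e0 = ndtr(hi[:, 0] / L[0, 0])[:, None]
    f = np.repeat(e0 - d0, M, axis=1)  # (R, M)
    dcur, ecur = np.repeat(d0, M, axis=1), np.repeat(e0, M, axis=1)
    for i in range(1, d):
        q = dcur + w[None, :, i - 1] * (ecur - dcur)
        y[:, :, i - 1] = ndtri(np.clip(q, _EPS, 1.0 - _EPS))
        partial = np.einsum("j,rmj->rm", L[i, : i], y[:, :, : i])
        dcur = ndtr((lo[:, i, None] - partial) / L[i, i])
        ecur = ndtr((hi[:, i, None] - partial) / L[i, i])
        f = f * np.clip(ecur - dcur, 0.0, 1.0)
    out = np.clip(f.mean(axis=1), 0.0, 1.0)
    # Empty rectangles can sneak through as tiny negatives; zero them exactly.
    out[np.any(lo >= hi, axis=1)] = 0.0
    return float(out[0]) if scalar_in else out


def _pivot_conditioned_probability(
    region: EventRegion,
    mean: np.ndarray,
    cov: np.ndarray,
    pivot: int,
    *,
    n_points: int,
    n_nodes: int,
) -> float:
    """Integrate out the pivot statistic, turning order constraints into bounds."""
    d = len(region.refs)
    rest = [i for i in range(d) if i != pivot]
    mp, sp2 = mean[pivot], cov[pivot, pivot]
    sp = np.sqrt(sp2)
    a = max(region.lower[pivot], mp - _TAIL * sp)
    b = min(region.upper[pivot], mp + _TAIL * sp)
    if a >= b:
        return 0.0
    x, wq = _leggauss(n_nodes)
    z = 0.5 * (b - a) * x + 0.5 * (b + a)  # pivot values, (N,)
    dens = np.exp(-0.5 * ((z - mp) / sp) ** 2) / (sp * np.sqrt(2.0 * np.pi))
    jac = 0.5 * (b - a)
    if not rest:
        return float(np.sum(wq * dens) * jac)

    slope = cov[rest, pivot] / sp2  # (d-1,)
    cond_cov = cov[np.ix_(rest, rest)] - np.outer(cov[rest, pivot], cov[pivot, rest]) / sp2
    cond_mean = mean[rest][None, :] + slope[None, :] * (z - mp)[:, None]  # (N, d-1)

    lo = np.tile(np.asarray(region.lower, dtype=float)[rest], (len(z), 1))
    hi = np.tile(np.asarray(region.upper, dtype=float)[rest], (len(z), 1))
    pos = {orig: new for new, orig in enumerate(rest)}
    for g, l in region.order_constraints:
        if g == pivot:  # refs[l] <= z
            j = pos[l]
            hi[:, j] = np.minimum(hi[:, j], z)
        else:  # l == pivot: refs[g] >= z
            j = pos[g]
            lo[:, j] = np.maximum(lo[:, j], z)
    inner = mvn_rectangle_prob(lo, hi, cond_mean, cond_cov, n_points=n_points)
    return float(np.sum(wq * dens * inner) * jac)


def region_probability(
    region: EventRegion,
    design: DesignSpec,
    means: ScenarioMeans,
    *,
    n_points: int = DEFAULT_QMC_POINTS,
    n_nodes: int = DEFAULT_QUAD_NODES,
    dim_cap: int = DIM_CAP,
) -> float:
    """Probability of the region under the joint Gaussian law of its statistics.

    Order constraints are eliminated either by conditioning on a shared
    pivot statistic (when every constraint involves the same statistic) or,
    failing that, by appending the difference of the constrained pair as an
    extra Gaussian coordinate bounded below by zero.
    """
    d = len(region.refs)
    if d > dim_cap:
        raise ValueError(f"region dimension {d} exceeds cap {dim_cap}")
    mean = np.array([drift(r, design, means) for r in region.refs])
    cov = covariance(region.refs, design)

    if not region.order_constraints:
        return float(
            mvn_rectangle_prob(
                np.asarray(region.lower), np.asarray(region.upper), mean, cov,
                n_points=n_points,
            )
        )

    # Prefer a pivot shared by every constraint.
    counts: dict[int, int] = {}
    for pair in region.order_constraints:
        for idx in pair:
            counts[idx] = counts.get(idx, 0) + 1
    n_con = len(region.order_constraints)
    shared = [i for i, c in counts.items() if c == n_con]
    if shared:
        return _pivot_conditioned_probability(
            region, mean, cov, shared[0], n_points=n_points, n_nodes=n_nodes
        )

    # Generic fallback: append difference coordinates (refs[g] - refs[b] >= 0),
    # dropping coordinates whose own bounds are vacuous so the augmented
    # covariance stays full-rank whenever possible.
    bounded = [i for i in range(d)
               if np.isfinite(region.lower[i]) or np.isfinite(region.upper[i])]
    if len(bounded) + n_con > dim_cap:
        raise ValueError("augmented region dimension exceeds cap")
    E = np.eye(d)
    rows = [E[i][None, :] for i in bounded]
    rows += [(E[g] - E[l])[None, :] for g, l in region.order_constraints]
    A = np.vstack(rows)
    aug_mean = A @ mean
    aug_cov = A @ cov @ A.T
    eig = np.linalg.eigvalsh(aug_cov)
    if eig.min() < 1e-10:
        raise ValueError(
            "order constraints make the augmented covariance singular; "
            "express them through a shared pivot statistic instead"
        )
    lo = np.concatenate([np.asarray(region.lower)[bounded], np.zeros(n_con)])
    hi = np.concatenate([np.asarray(region.upper)[bounded], np.full(n_con, np.inf)])
    return float(mvn_rectangle_prob(lo, hi, aug_mean, aug_cov, n_points=n_points))
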
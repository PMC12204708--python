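"""Scenario-grid evaluation of the retain-vs-discard policy contrast.

For a grid of treatment-effect pairs (mu1 - mu0, mu2 - mu0), with every
further arm held at a fixed offset, this module computes

* conditional power of the watched arm under both data policies, given the
  designated arm becomes the control at the change stage;
* the conditional type-I error contrast on the half-plane mu2 <= mu1 (above
  it, the watched arm is truly superior and no type-I error can be made);
* overall power under both policies for the best arm at each grid point;
* the probability that an arm without the greatest effect becomes the
  control at the first analysis.

Differences are reported in percentage points (discard minus retain).
Grid evaluation is embarrassingly parallel; a worker count above one
distributes points over processes without changing any result.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design_model import ChangeConfig, DesignSpec, ScenarioMeans
from .operating_characteristics import (
    ConditioningError,
    conditional_power_both,
    overall_power_both,
    wrong_control_probability,
)

__all__ = ["GridSpec", "run_grid", "surface_maxima"]

# Grid accuracy profile: the surfaces are compared at percentage-point
# scale, so the integration error (~1e-5) is far below what matters and the
# cheaper profile keeps a 31 x 31 grid to a few minutes on one CPU.
GRID_QMC_POINTS = 1 << 11
GRID_QUAD_NODES = 32

SURFACES = ("conditional_power", "conditional_type1", "overall_power", "wrong_control")


@dataclass(frozen=True)
class GridSpec:
    """Axis ranges and fixed quantities of a scenario grid.

    ``mu1`` is the effect of the arm that becomes control (``k_prime``),
    ``mu2`` the effect of the watched arm (``k_star``); arms other than
    these two sit at ``other_offset`` relative to the original control.
    """

    mu1_range: tuple[float, float] = (-0.5, 1.0)
    mu2_range: tuple[float, float] = (-0.5, 1.0)
    step: float = 0.05
    other_offset: float = 0.0
    k_prime: int = 1
    j_prime: int = 1
    k_star: int = 2
    surfaces: tuple[str, ...] = SURFACES

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValueError(f"step must be positive, got {self.step}")
        for lo, hi in (self.mu1_range, self.mu2_range):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid axis range ({lo}, {hi})")
        unknown = set(self.surfaces) - set(SURFACES)
        if unknown:
            raise ValueError(f"unknown surfaces: {sorted(unknown)}")

    def axis(self, which: int) -> np.ndarray:
        lo, hi = self.mu1_range if which == 1 else self.mu2_range
        n = int(round((hi - lo) / self.step))
        return np.round(lo + self.step * np.arange(n + 1), 10)


def _scenario(design: DesignSpec, grid: GridSpec, mu1: float, mu2: float) -> ScenarioMeans:
    mu = [0.0] * (design.K + 1)
    mu[grid.k_prime] = mu1
    mu[grid.k_star] = mu2
    for arm in range(1, design.K + 1):
        if arm not in (grid.k_prime, grid.k_star):
            mu[arm] = grid.other_offset
    return ScenarioMeans(mu=tuple(mu))


def _best_arm_lowest_index(means: ScenarioMeans) -> int:
    effects = np.asarray(means.mu[1:])
    return int(np.argmax(effects)) + 1  # ties broken towards the lowest index


def _evaluate_point(args) -> dict:
    design, grid, mu1, mu2, n_points, n_nodes = args
    means = _scenario(design, grid, mu1, mu2)
    change = ChangeConfig(k_prime=grid.k_prime, j_prime=grid.j_prime)
    kw = dict(n_points=n_points, n_nodes=n_nodes)
    row: dict = {"mu1": mu1, "mu2": mu2,
                 "mu_other": grid.other_offset, "flag": "ok"}

    if "conditional_power" in grid.surfaces or "conditional_type1" in grid.surfaces:
        try:
            retain, discard = conditional_power_both(design, means, change, grid.k_star, **kw)
            row.update(cond_power_retain=retain, cond_power_discard=discard,
                       cond_power_diff_pp=100.0 * (discard - retain))
        except ConditioningError:
            row.update(cond_power_retain=np.nan, cond_power_discard=np.nan,
                       cond_power_diff_pp=np.nan, flag="conditioning_error")
            retain = discard = np.nan
        if "conditional_type1" in grid.surfaces:
            # type-I errors exist only where the watched arm is not truly better
            defined = mu2 <= mu1
            row.update(
                cond_t1e_retain=retain if defined else np.nan,
                cond_t1e_discard=discard if defined else np.nan,
                cond_t1e_diff_pp=100.0 * (discard - retain) if defined else np.nan,
            )

    if "overall_power" in grid.surfaces:
        k_best = _best_arm_lowest_index(means)
        both = overall_power_both(design, means, k_best, **kw)
        r, d = both["retain"].overall_power, both["discard"].overall_power
        row.update(overall_retain=r, overall_discard=d,
                   overall_diff_pp=100.0 * (d - r), k_star_overall=k_best)

    if "wrong_control" in grid.surfaces:
        k_best = _best_arm_lowest_index(means)
        row["wrong_control_prob"] = wrong_control_probability(
            design, means, k_best, j_star=1, **kw
        )
    return row


def run_grid(
    design: DesignSpec,
    grid: GridSpec,
    *,
    n_points: int = GRID_QMC_POINTS,
    n_nodes: int = GRID_QUAD_NODES,
    workers: int = 1,
) -> pd.DataFrame:
    """Evaluate the requested surfaces at every grid point (long format)."""
    if not design.has_boundaries:
        raise ValueError("design has no boundaries; calibrate first")
    ChangeConfig(k_prime=grid.k_prime, j_prime=grid.j_prime).validate_for(design)
    if grid.k_star == grid.k_prime or not (1 <= grid.k_star <= design.K):
        raise ValueError("grid k_star must be a valid arm different from k_prime")
    tasks = [(design, grid, float(m1), float(m2), n_points, n_nodes)
             for m1 in grid.axis(1) for m2 in grid.axis(2)]
    if workers > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            rows = list(pool.map(_evaluate_point, tasks, chunksize=16))
    else:
        rows = [_evaluate_point(t) for t in tasks]
    return pd.DataFrame(rows)


def surface_maxima(table: pd.DataFrame) -> dict:
    """Headline maxima of a grid table, with the grid points attaining them.

    The conditional type-I contrast is maximised over the half-plane
    ``mu2 <= mu1`` only, where the quantity is defined.
    """
    if table.empty:
        raise ValueError("empty grid table")
    out: dict = {}

    def argmax(col: str, sub: pd.DataFrame | None = None, absolute: bool = False):
        df = table if sub is None else sub
        if col not in df or df[col].dropna().empty:
            raise ValueError(f"surface {col!r} is absent or entirely undefined")
        vals = df[col].abs() if absolute else df[col]
        i = vals.idxmax()
        return float(df.loc[i, col]), float(df.loc[i, "mu1"]), float(df.loc[i, "mu2"])

    if "cond_power_diff_pp" in table:
        v, m1, m2 = argmax("cond_power_diff_pp")
        out["max_cond_power_diff_pp"] = v
        out["argmax_cond_power_diff"] = (m1, m2)
    if "cond_t1e_diff_pp" in table:
        sub = table[table["mu2"] <= table["mu1"]]
        v, m1, m2 = argmax("cond_t1e_diff_pp", sub)
        out["max_cond_t1e_inflation_pp"] = v
        out["argmax_cond_t1e_inflation"] = (m1, m2)
        out["cond_t1e_argmax_on_diagonal"] = bool(np.isclose(m1, m2))
    if "overall_diff_pp" in table:
        v, m1, m2 = argmax("overall_diff_pp", absolute=True)
        out["max_overall_diff_pp"] = v
        out["argmax_overall_diff"] = (m1, m2)
    return out
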
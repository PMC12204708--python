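"""Domain types and configuration handling for platform-trial designs.

The trial model: ``K`` experimental arms are compared with one shared control
(arm 0) at ``J`` analyses.  Recruitment is balanced — every active arm
(including the control) recruits ``n_per_stage`` patients between consecutive
analyses, so the cumulative per-arm sample size at analysis ``j`` is
``j * n_per_stage``.  Responses are independent normal with known standard
deviation ``sigma``.  At each analysis an arm whose standardised test
statistic exceeds the upper boundary ``u_j`` is declared superior; the first
such arm (the one with the largest statistic if several cross at once)
becomes the new control for the remainder of the trial.  An arm whose
statistic falls below the lower boundary ``l_j`` is dropped for futility.
The final analysis is binding: ``l_J == u_J``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import yaml

__all__ = [
    "DesignSpec",
    "ScenarioMeans",
    "ChangeConfig",
    "OCResult",
    "TrialConfig",
    "load_config",
    "serialize_config",
]

Policy = Literal["retain", "discard"]
VALID_POLICIES = ("retain", "discard")


class ConfigError(ValueError):
    """Raised when a configuration violates a design invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class DesignSpec:
    """Static design of a multi-arm multi-stage trial.

    Boundaries may be omitted (``upper is None``) when ``boundary_shape`` is
    given; :func:`controlswitch.calibration.ensure_boundaries` then fills them
    by calibrating the shape constant to ``alpha_fwer``.
    """

    K: int
    J: int
    n_per_stage: int
    sigma: float = 1.0
    upper: tuple[float, ...] | None = None
    lower: tuple[float, ...] | None = None
    boundary_shape: str | None = None
    alpha_fwer: float = 0.05
    theta1: float | None = None
    theta0: float | None = None
    power_target: float | None = None

    def __post_init__(self) -> None:
        _require(int(self.K) == self.K and self.K >= 1, f"K must be an integer >= 1, got {self.K}")
        _require(int(self.J) == self.J and self.J >= 1, f"J must be an integer >= 1, got {self.J}")
        _require(
            int(self.n_per_stage) == self.n_per_stage and self.n_per_stage >= 1,
            f"n_per_stage must be an integer >= 1, got {self.n_per_stage}",
        )
        _require(self.sigma > 0, f"sigma must be > 0, got {self.sigma}")
        _require(0.0 < self.alpha_fwer < 1.0, f"alpha_fwer must lie in (0, 1), got {self.alpha_fwer}")
        if self.power_target is not None:
            _require(0.0 < self.power_target < 1.0, f"power_target must lie in (0, 1), got {self.power_target}")
        if (self.upper is None) != (self.lower is None):
            raise ConfigError("upper and lower boundaries must be supplied together")
        if self.upper is None:
            _require(
                self.boundary_shape is not None,
                "either explicit boundaries or a boundary_shape must be given",
            )
        else:
            object.__setattr__(self, "upper", tuple(float(u) for u in self.upper))
            object.__setattr__(self, "lower", tuple(float(l) for l in self.lower))
            _require(len(self.upper) == self.J, f"upper must have length J={self.J}, got {len(self.upper)}")
            _require(len(self.lower) == self.J, f"lower must have length J={self.J}, got {len(self.lower)}")
            for j in range(self.J - 1):
                _require(
                    self.lower[j] <= self.upper[j],
                    f"lower[{j + 1}]={self.lower[j]} exceeds upper[{j + 1}]={self.upper[j]}",
                )
            _require(
                math.isclose(self.lower[-1], self.upper[-1], rel_tol=0.0, abs_tol=1e-9),
                f"final analysis must be binding: l_J={self.lower[-1]} != u_J={self.upper[-1]}",
            )
        if self.boundary_shape is not None:
            _require(self.boundary_shape == "triangular", f"unknown boundary_shape {self.boundary_shape!r}")

    @property
    def has_boundaries(self) -> bool:
        return self.upper is not None

    def n_cum(self, j: int) -> int:
        """Cumulative per-arm sample size at analysis ``j`` (1-based)."""
        _require(1 <= j <= self.J, f"stage {j} outside 1..{self.J}")
        return j * self.n_per_stage

    @property
    def total_max_n(self) -> int:
        """Maximum total sample size if no arm ever stops early."""
        return self.n_per_stage * self.J * (self.K + 1)

    def with_boundaries(self, upper: Sequence[float], lower: Sequence[float]) -> "DesignSpec":
        return dataclasses.replace(self, upper=tuple(upper), lower=tuple(lower))


@dataclass(frozen=True)
class ScenarioMeans:
    """True mean responses (mu_0, mu_1, ..., mu_K); arm 0 is the initial control."""

    mu: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", tuple(float(m) for m in self.mu))
        _require(len(self.mu) >= 2, "scenario needs at least a control and one experimental arm")
        _require(all(math.isfinite(m) for m in self.mu), "all means must be finite")

    @property
    def K(self) -> int:
        return len(self.mu) - 1

    def effect(self, k: int) -> float:
        """Treatment effect mu_k - mu_0 of experimental arm ``k``."""
        return self.mu[k] - self.mu[0]


@dataclass(frozen=True)
class ChangeConfig:
    """Which arm becomes the new control, at which stage, and the data policy."""

    k_prime: int
    j_prime: int
    policy: Policy = "discard"

    def __post_init__(self) -> None:
        _require(self.k_prime >= 1, f"k_prime must be >= 1, got {self.k_prime}")
        _require(self.j_prime >= 1, f"j_prime must be >= 1, got {self.j_prime}")
        _require(self.policy in VALID_POLICIES, f"policy must be one of {VALID_POLICIES}, got {self.policy!r}")

    def validate_for(self, design: DesignSpec) -> None:
        _require(self.k_prime <= design.K, f"k_prime={self.k_prime} exceeds K={design.K}")
        _require(
            self.j_prime <= design.J - 1,
            f"j_prime={self.j_prime} must leave at least one post-change analysis (J={design.J})",
        )


@dataclass
class OCResult:
    """Operating characteristics of one (scenario, policy) evaluation.

    ``conditional_type1`` is ``None`` when the scenario has
    mu_{k_star} > mu_{k_prime}, in which case no type-I error can be made.
    ``xi_terms[j]`` is the probability the best arm becomes control at stage
    ``j+1``; ``omega_terms[(k_prime, j_prime)]`` the probability another arm
    becomes control at ``j_prime`` and the best arm later beats it.
    """

    policy: Policy
    scenario: ScenarioMeans
    conditional_power: float | None = None
    conditional_type1: float | None = None
    overall_power: float | None = None
    xi_terms: tuple[float, ...] = ()
    omega_terms: dict = field(default_factory=dict)
    standard_errors: dict = field(default_factory=dict)
    n_replicates: int | None = None

    def check(self, tol: float = 1e-6) -> None:
        probs = [self.conditional_power, self.conditional_type1, self.overall_power]
        probs += list(self.xi_terms) + list(self.omega_terms.values())
        for p in probs:
            if p is not None and not (-tol <= p <= 1.0 + tol):
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.overall_power is not None and self.xi_terms:
            total = sum(self.xi_terms) + sum(self.omega_terms.values())
            if abs(total - self.overall_power) > max(tol, 1e-8):
                raise ValueError(
                    f"overall power {self.overall_power} != xi+omega total {total}"
                )


@dataclass(frozen=True)
class TrialConfig:
    """A parsed configuration file: design plus evaluation scenarios."""

    design: DesignSpec
    scenarios: tuple[ScenarioMeans, ...]
    change: ChangeConfig | None = None
    policies: tuple[Policy, ...] = ("retain", "discard")


_DESIGN_KEYS = {
    "K", "J", "n_per_stage", "sigma", "upper", "lower", "boundary_shape",
    "alpha_fwer", "theta1", "theta0", "power_target",
}
_TOP_KEYS = _DESIGN_KEYS | {"scenarios", "change", "policies"}


def load_config(path: str | Path) -> TrialConfig:
    """Parse and validate a YAML/JSON trial configuration.

    Returns the design, the scenario list (possibly empty) and the optional
    change record.  Defaults: ``sigma = 1``; both data policies evaluated.
    """
    path = Path(path)
    _require(path.exists(), f"config file not found: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    _require(isinstance(raw, dict), "config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    _require(not unknown, f"unknown config keys: {sorted(unknown)}")
    for key in ("K", "J", "n_per_stage"):
        _require(key in raw, f"missing required config key: {key}")

    design = DesignSpec(**{k: raw[k] for k in _DESIGN_KEYS if k in raw})

    scenarios = []
    for i, sc in enumerate(raw.get("scenarios", []) or []):
        _require(isinstance(sc, dict) and "mu" in sc, f"scenarios[{i}] must be a mapping with key 'mu'")
        means = ScenarioMeans(mu=sc["mu"])
        _require(
            means.K == design.K,
            f"scenarios[{i}].mu must have length K+1={design.K + 1}, got {len(means.mu)}",
        )
        scenarios.append(means)

    change = None
    if raw.get("change") is not None:
        ch = raw["change"]
        _require(isinstance(ch, dict), "change must be a mapping")
        change = ChangeConfig(
            k_prime=ch.get("k_prime", 1),
            j_prime=ch.get("j_prime", 1),
            policy=ch.get("policy", "discard"),
        )
        change.validate_for(design)

    policies = tuple(raw.get("policies", ("retain", "discard")))
    for p in policies:
        _require(p in VALID_POLICIES, f"policy must be one of {VALID_POLICIES}, got {p!r}")

    return TrialConfig(design=design, scenarios=tuple(scenarios), change=change, policies=policies)


def serialize_config(config: TrialConfig) -> str:
    """YAML serialisation of a config; round-trips through :func:`load_config`."""
    d = config.design
    out: dict = {"K": d.K, "J": d.J, "n_per_stage": d.n_per_stage, "sigma": d.sigma,
                 "alpha_fwer": d.alpha_fwer}
    if d.upper is not None:
        out["upper"] = list(d.upper)
        out["lower"] = list(d.lower)
    if d.boundary_shape is not None:
        out["boundary_shape"] = d.boundary_shape
    for key in ("theta1", "theta0", "power_target"):
        val = getattr(d, key)
        if val is not None:
            out[key] = val
    if config.scenarios:
        out["scenarios"] = [{"mu": list(s.mu)} for s in config.scenarios]
    if config.change is not None:
        out["change"] = {
            "k_prime": config.change.k_prime,
            "j_prime": config.change.j_prime,
            "policy": config.change.policy,
        }
    out["policies"] = list(config.policies)
    return yaml.safe_dump(out, sort_keys=False)
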
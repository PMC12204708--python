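import numpy as np
import pytest

from controlswitch import DesignSpec, ScenarioMeans, calibrate_constant


@pytest.fixture(scope="session")
def tailor_printed() -> DesignSpec:
    """The motivating four-arm design with its published boundary table."""
    return DesignSpec(
        K=3, J=2, n_per_stage=43, sigma=1.0,
        upper=(2.358, 2.223), lower=(0.786, 2.223),
        alpha_fwer=0.05, theta1=0.545, theta0=0.178, power_target=0.9,
    )


@pytest.fixture(scope="session")
def tailor_calibrated() -> DesignSpec:
    """The same design with boundaries calibrated exactly by this package."""
    shape = calibrate_constant(3, 2, 0.05)
    upper, lower = shape.boundaries(2)
    return DesignSpec(
        K=3, J=2, n_per_stage=43, sigma=1.0, upper=upper, lower=lower,
        alpha_fwer=0.05, theta1=0.545, theta0=0.178, power_target=0.9,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_design(rng: np.random.Generator, *, K=None, J=None,
                  lower_mode="nonnegative") -> DesignSpec:
    """A random small design satisfying the ordering-theorem premises.

    ``lower_mode``: ``nonnegative`` draws 0 <= l_j <= u_j; ``none`` uses no
    futility boundaries (l_j = -inf before the final analysis).  The final
    analysis is always binding (l_J = u_J >= 0).
    """
    K = int(rng.integers(2, 4)) if K is None else K
    J = int(rng.integers(2, 4)) if J is None else J
    u = np.sort(rng.uniform(0.2, 3.0, size=J))[::-1].copy()
    if lower_mode == "nonnegative":
        l = rng.uniform(0.0, u[:-1])
    elif lower_mode == "none":
        l = np.full(J - 1, -np.inf)
    else:
        raise ValueError(lower_mode)
    lower = tuple(l) + (u[-1],)
    return DesignSpec(K=K, J=J, n_per_stage=int(rng.integers(5, 60)),
                      sigma=float(rng.uniform(0.5, 2.0)),
                      upper=tuple(u), lower=lower)


def random_scenario(rng: np.random.Generator, K: int) -> ScenarioMeans:
    mu0 = float(rng.uniform(-1, 1))
    return ScenarioMeans(mu=(mu0, *(mu0 + rng.uniform(-0.8, 0.8, size=K))))
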
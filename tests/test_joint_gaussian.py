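"""Joint Gaussian law of the test statistics and rectangle probabilities.

The rectangle engine is cross-checked against scipy's multivariate normal
CDF (an independent implementation of the same integral) and against plain
Monte Carlo; drifts and covariances are checked against hand-derived values
and, in the simulator tests, against patient-level moments.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal as scipy_mvn
from scipy.stats import norm

from controlswitch.design_model import DesignSpec, ScenarioMeans
from controlswitch.joint_gaussian import (
    EventRegion,
    StatisticRef,
    covariance,
    drift,
    mvn_rectangle_prob,
    region_probability,
)

D = DesignSpec(K=3, J=2, n_per_stage=43, sigma=1.0,
               upper=(2.358, 2.223), lower=(0.786, 2.223))
NULL = ScenarioMeans(mu=(0.0, 0.0, 0.0, 0.0))


class TestDrift:
    def test_pre_change_statistic(self):
        means = ScenarioMeans(mu=(0.0, 0.545, 0.0, 0.0))
        got = drift(StatisticRef("pre", k=1, j=1), D, means)
        assert got == pytest.approx(0.545 * np.sqrt(43 / 2), rel=1e-12)

    def test_null_symmetry(self):
        for ref in [
            StatisticRef("pre", k=2, j=2),
            StatisticRef("retained", k=2, j=2, comparator=1),
            StatisticRef("post_only", k=2, j=2, comparator=1, j_prime=1),
        ]:
            assert drift(ref, D, NULL) == pytest.approx(0.0, abs=1e-14)

    def test_post_only_statistic(self):
        means = ScenarioMeans(mu=(0.0, 0.0, 1.0, 0.0))
        got = drift(StatisticRef("post_only", k=2, j=2, comparator=1, j_prime=1), D, means)
        assert got == pytest.approx(np.sqrt(43 / 2), rel=1e-12)

    def test_sigma_scales_out(self):
        d2 = DesignSpec(K=3, J=2, n_per_stage=43, sigma=2.0,
                        upper=D.upper, lower=D.lower)
        means = ScenarioMeans(mu=(0.0, 0.545, 0.0, 0.0))
        assert drift(StatisticRef("pre", k=1, j=1), d2, means) == pytest.approx(
            0.545 * np.sqrt(43 / 2) / 2.0
        )


class TestCovariance:
    def test_group_sequential_same_arm(self):
        cov = covariance([StatisticRef("pre", k=1, j=1), StatisticRef("pre", k=1, j=2)], D)
        assert cov[0, 1] == pytest.approx(np.sqrt(43 / 86), rel=1e-12)

    def test_shared_control_same_stage(self):
        cov = covariance([StatisticRef("pre", k=1, j=1), StatisticRef("pre", k=2, j=1)], D)
        assert cov[0, 1] == pytest.approx(0.5, rel=1e-12)

    def test_post_only_independent_of_pre(self):
        cov = covariance(
            [StatisticRef("post_only", k=2, j=2, comparator=1, j_prime=1),
             StatisticRef("pre", k=2, j=1)], D,
        )
        assert cov[0, 1] == pytest.approx(0.0, abs=1e-14)

    def test_retained_vs_pre(self):
        # expanding both sums over patient responses: shared arm-2 stage-1 block
        cov = covariance(
            [StatisticRef("retained", k=2, j=2, comparator=1),
             StatisticRef("pre", k=2, j=1)], D,
        )
        assert cov[0, 1] == pytest.approx(0.5 * np.sqrt(43 / 86), rel=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(data=st.data())
    def test_random_ref_sets_are_psd_with_unit_diagonal(self, data):
        K, J = 3, 3
        d = DesignSpec(K=K, J=J, n_per_stage=data.draw(st.integers(1, 100)),
                       sigma=data.draw(st.floats(0.1, 5.0)),
                       upper=(3.0, 2.5, 2.0), lower=(0.0, 0.5, 2.0))
        jp = data.draw(st.integers(1, J - 1))
        pool = (
            [StatisticRef("pre", k=k, j=j) for k in (1, 2, 3) for j in (1, 2, 3)]
            + [StatisticRef("retained", k=k, j=j, comparator=1)
               for k in (2, 3) for j in range(jp + 1, J + 1)]
            + [StatisticRef("post_only", k=k, j=j, comparator=1, j_prime=jp)
               for k in (2, 3) for j in range(jp + 1, J + 1)]
        )
        refs = data.draw(st.lists(st.sampled_from(pool), min_size=1, max_size=6,
                                  unique=True))
        cov = covariance(refs, d)
        assert np.allclose(np.diag(cov), 1.0, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() >= -1e-10
        assert np.all(np.abs(cov) <= 1.0 + 1e-12)

    def test_unit_diagonal_and_psd(self, rng):
        refs = [
            StatisticRef("pre", k=1, j=1), StatisticRef("pre", k=1, j=2),
            StatisticRef("pre", k=2, j=1), StatisticRef("pre", k=3, j=2),
            StatisticRef("retained", k=2, j=2, comparator=1),
            StatisticRef("post_only", k=3, j=2, comparator=1, j_prime=1),
        ]
        cov = covariance(refs, D)
        assert np.allclose(np.diag(cov), 1.0)
        assert np.linalg.eigvalsh(cov).min() >= -1e-10
        assert np.allclose(cov, cov.T)


class TestRectangleEngine:
    def test_half_line_is_half(self):
        region = EventRegion((StatisticRef("pre", k=1, j=1),), (-np.inf,), (0.0,))
        assert region_probability(region, D, NULL) == pytest.approx(0.5, abs=1e-9)

    def test_independent_region_factorises(self):
        # pre statistic at stage 1 and post-only at stage 2 are independent
        refs = (StatisticRef("pre", k=3, j=1),
                StatisticRef("post_only", k=2, j=2, comparator=1, j_prime=1))
        region = EventRegion(refs, (-1.0, 0.5), (1.0, np.inf))
        expected = (norm.cdf(1) - norm.cdf(-1)) * (1 - norm.cdf(0.5))
        assert region_probability(region, D, NULL) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("dim", [2, 3, 5])
    def test_matches_scipy_cdf(self, dim, rng):
        A = rng.normal(size=(dim, dim + 2))
        cov = A @ A.T
        cov = cov / np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        mean = rng.normal(scale=0.5, size=dim)
        lo = rng.uniform(-2.5, -0.5, size=dim)
        hi = lo + rng.uniform(0.5, 3.0, size=dim)
        ours = mvn_rectangle_prob(lo, hi, mean, cov)
        ref = scipy_mvn.cdf(hi, mean=mean, cov=cov, lower_limit=lo,
                            abseps=1e-8, maxpts=2_000_000)
        assert ours == pytest.approx(ref, abs=5e-6)

    def test_matches_monte_carlo_oracle(self):
        cov = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]])
        mean = np.array([0.2, -0.3, 0.1])
        lo = np.array([-1.0, -np.inf, 0.0])
        hi = np.array([1.5, 1.0, np.inf])
        gen = np.random.default_rng(7)
        draws = gen.multivariate_normal(mean, cov, size=10_000_000)
        inside = np.all((draws >= lo) & (draws <= hi), axis=1)
        mc = inside.mean()
        se = np.sqrt(mc * (1 - mc) / inside.size)
        assert mvn_rectangle_prob(lo, hi, mean, cov) == pytest.approx(mc, abs=3 * se)

    def test_batched_equals_individual(self):
        cov = np.array([[1.0, 0.3], [0.3, 1.0]])
        his = np.array([[0.5, 1.0], [1.5, 2.0], [0.0, 0.0]])
        los = np.full_like(his, -np.inf)
        batch = mvn_rectangle_prob(los, his, np.zeros(2), cov)
        single = [mvn_rectangle_prob(los[i], his[i], np.zeros(2), cov) for i in range(3)]
        assert np.allclose(batch, single)

    def test_deterministic_across_calls(self):
        cov = np.array([[1.0, 0.4], [0.4, 1.0]])
        a = mvn_rectangle_prob([-1, -1], [1, 1], [0, 0], cov)
        b = mvn_rectangle_prob([-1, -1], [1, 1], [0, 0], cov)
        assert a == b

    def test_empty_rectangle_is_zero(self):
        cov = np.eye(2)
        assert mvn_rectangle_prob([1.0, 0.0], [0.5, 1.0], [0, 0], cov) == 0.0


class TestRegionProperties:
    def test_monotone_in_bounds(self):
        refs = (StatisticRef("pre", k=1, j=1), StatisticRef("pre", k=2, j=1))
        probs = [
            region_probability(EventRegion(refs, (-np.inf, -np.inf), (b, 1.0)), D, NULL)
            for b in (-1.0, 0.0, 1.0, 2.0)
        ]
        assert all(p2 >= p1 - 1e-9 for p1, p2 in zip(probs, probs[1:]))

    def test_complement_partition_sums_to_one(self):
        refs = (StatisticRef("pre", k=1, j=1), StatisticRef("pre", k=2, j=1))
        cut = 0.3
        quadrants = [
            EventRegion(refs, (-np.inf, -np.inf), (cut, cut)),
            EventRegion(refs, (cut, -np.inf), (np.inf, cut)),
            EventRegion(refs, (-np.inf, cut), (cut, np.inf)),
            EventRegion(refs, (cut, cut), (np.inf, np.inf)),
        ]
        total = sum(region_probability(q, D, NULL) for q in quadrants)
        assert total == pytest.approx(1.0, abs=5e-6)

    def test_dimension_cap(self):
        refs = tuple(StatisticRef("pre", k=k, j=j) for k in (1, 2, 3) for j in (1, 2))
        region = EventRegion(refs, (-np.inf,) * 6, (np.inf,) * 6)
        with pytest.raises(ValueError, match="cap"):
            region_probability(region, D, NULL, dim_cap=5)

    def test_inconsistent_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            EventRegion((StatisticRef("pre", k=1, j=1),), (1.0,), (0.0,))


class TestOrderConstraints:
    """The largest-crosser tie rule as an ordering against a pivot."""

    def _mc(self, mean, cov, checker, n=4_000_000, seed=11):
        draws = np.random.default_rng(seed).multivariate_normal(mean, cov, size=n)
        hits = checker(draws)
        p = hits.mean()
        return p, np.sqrt(p * (1 - p) / n)

    def test_pivot_conditioning_matches_monte_carlo(self):
        # P(Z1 > u, Z2 in [l, inf), Z2 < Z1): two arms, shared control
        refs = (StatisticRef("pre", k=1, j=1), StatisticRef("pre", k=2, j=1))
        means = ScenarioMeans(mu=(0.0, 0.3, 0.2, 0.0))
        region = EventRegion(refs, (1.0, -0.5), (np.inf, np.inf), ((0, 1),))
        mean = np.array([drift(r, D, means) for r in refs])
        cov = covariance(refs, D)
        mc, se = self._mc(mean, cov, lambda d: (d[:, 0] > 1.0) & (d[:, 1] > -0.5)
                          & (d[:, 1] <= d[:, 0]))
        assert region_probability(region, D, means) == pytest.approx(mc, abs=3 * se)

    def test_two_constraints_shared_pivot(self):
        # both remaining arms must sit below the incoming control
        refs = (StatisticRef("pre", k=1, j=1), StatisticRef("pre", k=2, j=1),
                StatisticRef("pre", k=3, j=1))
        region = EventRegion(refs, (1.5, -np.inf, -np.inf), (np.inf,) * 3,
                             ((0, 1), (0, 2)))
        mean = np.zeros(3)
        cov = covariance(refs, D)
        mc, se = self._mc(mean, cov, lambda d: (d[:, 0] > 1.5)
                          & (d[:, 1] <= d[:, 0]) & (d[:, 2] <= d[:, 0]))
        assert region_probability(region, D, NULL) == pytest.approx(mc, abs=3 * se)

    def test_difference_augmentation_fallback(self):
        # constraints without a shared pivot fall back to appended differences
        refs = (StatisticRef("pre", k=1, j=1), StatisticRef("pre", k=2, j=1),
                StatisticRef("pre", k=3, j=1), StatisticRef("pre", k=3, j=2))
        region = EventRegion(refs, (-np.inf,) * 4, (np.inf, 1.0, np.inf, 0.5),
                             ((0, 1), (3, 2)))
        mean = np.zeros(4)
        cov = covariance(refs, D)
        mc, se = self._mc(mean, cov, lambda d: (d[:, 1] <= 1.0) & (d[:, 3] <= 0.5)
                          & (d[:, 1] <= d[:, 0]) & (d[:, 2] <= d[:, 3]))
        assert region_probability(region, D, NULL) == pytest.approx(mc, abs=3 * se)
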
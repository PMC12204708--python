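"""Event construction, conditional power/type-I error and overall power.

The theorem-style ordering properties (retaining pre-change data never
helps the watched arm when the boundaries are non-negative, or when there
are no futility boundaries) are exercised here on randomized designs; the
full-size suites live with the acceptance tests.
"""

import numpy as np
import pytest
from scipy.stats import norm

from controlswitch.calibration import pairwise_power
from controlswitch.design_model import ChangeConfig, DesignSpec, ScenarioMeans
from controlswitch.joint_gaussian import covariance, drift
from controlswitch.operating_characteristics import (
    ConditioningError,
    build_events,
    conditional_power,
    conditional_power_both,
    conditional_type1,
    overall_power,
    overall_power_both,
    wrong_control_probability,
)

from conftest import random_design, random_scenario

CH = ChangeConfig(k_prime=1, j_prime=1)


class TestBuildEvents:
    def test_two_stage_events_collapse_to_single_statistics(self, tailor_printed):
        ev = build_events(tailor_printed, CH, k_star=2)
        (e1,) = ev["E1"].regions
        assert len(e1.refs) == 1 and e1.refs[0].kind == "pre" and e1.refs[0].k == 1
        assert e1.lower == (tailor_printed.upper[0],)
        (e4s,) = ev["E4_star"].regions
        assert len(e4s.refs) == 1 and e4s.refs[0].kind == "post_only"
        assert e4s.lower == (tailor_printed.upper[1],)
        (e4,) = ev["E4"].regions
        assert [r.kind for r in e4.refs] == ["retained"]
        assert e4.refs[0].j == 2 and e4.refs[0].comparator == 1

    def test_three_stage_rejection_event_is_disjoint_union(self, rng):
        d = DesignSpec(K=2, J=3, n_per_stage=10,
                       upper=(2.8, 2.4, 2.0), lower=(0.0, 0.5, 2.0))
        ev = build_events(d, CH, k_star=2)
        regions = ev["E4"].regions
        assert len(regions) == 2  # reject at stage 2, or continue then reject at 3
        # empirical disjointness on the joint law of the retained statistics
        refs = regions[1].refs
        mean = np.array([drift(r, d, ScenarioMeans(mu=(0, 0.2, 0.4))) for r in refs])
        cov = covariance(refs, d)
        draws = rng.multivariate_normal(mean, cov, size=200_000)
        in_first = draws[:, 0] > d.upper[1]
        in_second = ((draws[:, 0] >= d.lower[1]) & (draws[:, 0] <= d.upper[1])
                     & (draws[:, 1] > d.upper[2]))
        assert not np.any(in_first & in_second)

    def test_k_star_equal_k_prime_rejected(self, tailor_printed):
        with pytest.raises(ValueError, match="k_star"):
            build_events(tailor_printed, CH, k_star=1)


class TestConditionalPower:
    def test_discard_closed_form_at_equal_means(self, tailor_printed):
        # with one remaining analysis, the discard rejection event is a
        # single Gaussian tail: 1 - Phi(u_2)
        means = ScenarioMeans(mu=(0.0, 0.3, 0.3, 0.0))
        got = conditional_power(tailor_printed, means,
                                ChangeConfig(k_prime=1, j_prime=1, policy="discard"), 2)
        assert got == pytest.approx(1 - norm.cdf(2.223), abs=1e-9)

    def test_negligible_conditioning_raises(self, tailor_printed):
        d = tailor_printed.with_boundaries((40.0, 2.223), (0.786, 2.223))
        with pytest.raises(ConditioningError, match="negligible"):
            conditional_power(d, ScenarioMeans(mu=(0, 0, 0, 0)), CH, 2)

    def test_strict_crosser_variant_shrinks_conditioning(self, tailor_printed):
        # forcing same-stage crossers out can only remove probability mass
        from controlswitch.operating_characteristics import _conditioning_regions
        from controlswitch.joint_gaussian import region_probability
        means = ScenarioMeans(mu=(0.0, 0.4, 0.3, 0.1))
        den = {
            flag: sum(
                region_probability(r, tailor_printed, means)
                for r in _conditioning_regions(tailor_printed, 1, 1, 2,
                                               crossers_remain_active=flag)
            )
            for flag in (True, False)
        }
        assert den[False] <= den[True] + 1e-9

    @pytest.mark.parametrize("lower_mode", ["nonnegative", "none"])
    def test_retain_never_beats_discard_under_theorem_premises(self, rng, lower_mode):
        # small randomized suite; the full-size one runs with the acceptance tests
        done = 0
        while done < 40:
            d = random_design(rng, lower_mode=lower_mode)
            sc = random_scenario(rng, d.K)
            jp = int(rng.integers(1, d.J))
            ks, kp = (2, 1) if rng.random() < 0.5 else (1, 2)
            try:
                retain, discard = conditional_power_both(
                    d, sc, ChangeConfig(k_prime=kp, j_prime=jp), ks)
            except ConditioningError:
                continue
            assert retain <= discard + 1e-6, (d, sc, jp, kp, ks)
            done += 1


class TestConditionalType1:
    def test_matches_conditional_power_at_equal_means(self, tailor_printed):
        means = ScenarioMeans(mu=(0.0, 0.2, 0.2, 0.0))
        ch = ChangeConfig(k_prime=1, j_prime=1, policy="discard")
        assert conditional_type1(tailor_printed, means, ch, 2) == pytest.approx(
            conditional_power(tailor_printed, means, ch, 2)
        )

    def test_undefined_when_watched_arm_truly_better(self, tailor_printed):
        means = ScenarioMeans(mu=(0.0, 0.1, 0.5, 0.0))
        assert conditional_type1(tailor_printed, means, CH, 2) is None


class TestOverallPower:
    def test_single_arm_reduces_to_pairwise_power(self, tailor_printed):
        d = DesignSpec(K=1, J=2, n_per_stage=43, upper=tailor_printed.upper,
                       lower=tailor_printed.lower)
        means = ScenarioMeans(mu=(0.0, 0.545))
        res = overall_power(d, means, "retain")
        assert not any(res.omega_terms.values())
        assert res.overall_power == pytest.approx(
            pairwise_power(43, d, 0.545), abs=1e-5
        )

    def test_decomposition_consistency(self, tailor_printed):
        means = ScenarioMeans(mu=(0.0, 0.3, 0.6, -0.1))
        res = overall_power(tailor_printed, means, "discard")
        assert res.overall_power == pytest.approx(
            sum(res.xi_terms) + sum(res.omega_terms.values())
        )
        assert 0.0 <= res.overall_power <= 1.0
        assert all(v >= 0 for v in res.xi_terms)
        assert all(v >= 0 for v in res.omega_terms.values())
        # a change at the final analysis leaves nothing to reject against
        assert res.omega_terms[(1, 2)] == 0.0 and res.omega_terms[(3, 2)] == 0.0

    def test_tied_best_arms_require_explicit_choice(self, tailor_printed):
        means = ScenarioMeans(mu=(0.0, 0.5, 0.5, 0.0))
        with pytest.raises(ValueError, match="k_star"):
            overall_power(tailor_printed, means, "retain")
        res = overall_power(tailor_printed, means, "retain", k_star=1)
        assert 0.0 <= res.overall_power <= 1.0

    def test_retain_never_beats_discard_under_theorem_premises(self, rng):
        done = 0
        while done < 25:
            d = random_design(rng, K=2, J=2)
            sc = random_scenario(rng, d.K)
            try:
                both = overall_power_both(d, sc)
            except ValueError:
                continue
            assert (both["retain"].overall_power
                    <= both["discard"].overall_power + 1e-6), (d, sc)
            done += 1

    def test_wrong_control_probability_null_is_symmetric(self, tailor_printed):
        means = ScenarioMeans(mu=(0.0, 0.2, 0.0, 0.0))
        p = wrong_control_probability(tailor_printed, means, 1)
        # both non-best arms sit at the control mean: each contributes equally
        from controlswitch.operating_characteristics import becomes_control_probability
        p2 = becomes_control_probability(tailor_printed, means, 2, 1)
        p3 = becomes_control_probability(tailor_printed, means, 3, 1)
        assert p == pytest.approx(p2 + p3, abs=1e-9)
        assert p2 == pytest.approx(p3, abs=1e-5)
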
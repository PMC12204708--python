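"""Patient-level Monte Carlo simulation of the platform trial.

The simulator realises the decision rules directly: at each analysis every
active experimental arm is compared with the current control; a statistic
above the upper boundary is a superiority declaration — the first time this
happens the largest crosser becomes the new control — and a statistic below
the lower boundary drops the arm for futility.  After the single control
change the remaining arms are tested against the new control with either
the retained (all-data) or the post-change-only statistic.

Both data policies are evaluated on the *same* simulated patient responses
(common random numbers): the policies share every pre-change trajectory and
differ only through the post-change test statistics, which makes policy
contrasts and discordance tables low-variance.

Test statistics are computed in realised-count form,
``(mean_k - mean_c) / (sigma * sqrt(1/N_k + 1/N_c))``, which reduces to the
standard balanced form when every arm recruits exactly ``n_per_stage``
patients per stage and also covers the simple-random-allocation experiment,
where per-arm stage totals are multinomial.  In that experiment the
randomisation list is fixed at trial start (patients are allocated equally
across all original arms throughout; responses of de-activated arms are
simply never used), which keeps the two policies on identical patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design_model import ChangeConfig, DesignSpec, OCResult, Policy, ScenarioMeans

__all__ = [
    "TrialPath",
    "simulate_trial",
    "estimate_oc",
    "estimate_fwer",
    "random_allocation_experiment",
    "run_cohort",
]

_STATUS = {
    "became_control": "became_control",
    "rejected_new": "rejected_vs_new_control",
    "rejected_orig": "rejected_vs_original_control",
    "dropped": "dropped_futility",
    "completed": "completed_without_rejection",
}


@dataclass
class TrialPath:
    """One realised trial: statistics, the change record, and arm statuses."""

    z_pre: np.ndarray  # (K+1, J); NaN where not computed; arm 0 row all NaN
    z_post: dict  # policy -> (K+1, J) post-change statistics
    change: tuple[int, int] | None  # (k_prime, j_prime) or None
    status: dict  # policy -> {arm: status string}
    seed: int | None = None


def _cumulative_sums(
    design: DesignSpec, means: ScenarioMeans, n_reps: int, rng: np.random.Generator,
    chunk: int = 200_000,
) -> np.ndarray:
    """Cumulative per-arm response sums, built from patient-level draws."""
    K, J, n = design.K, design.J, design.n_per_stage
    S = np.empty((n_reps, K + 1, J))
    for start in range(0, n_reps, chunk):
        stop = min(start + chunk, n_reps)
        for k in range(K + 1):
            for j in range(J):
                draws = rng.normal(means.mu[k], design.sigma, size=(stop - start, n))
                S[start:stop, k, j] = draws.sum(axis=1)
    np.cumsum(S, axis=2, out=S)
    return S


def _random_allocation_sums(
    design: DesignSpec, means: ScenarioMeans, n_reps: int, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative sums and counts under per-patient simple random allocation.

    Each stage recruits ``n_per_stage * (K+1)`` patients allocated uniformly
    across the K+1 original arms; arm response sums are drawn exactly as
    ``N(count * mu, count * sigma^2)``.
    """
    K, J, n = design.K, design.J, design.n_per_stage
    total = n * (K + 1)
    counts = rng.multinomial(total, np.full(K + 1, 1.0 / (K + 1)), size=(n_reps, J))
    counts = counts.transpose(0, 2, 1).astype(float)  # (R, K+1, J) stage increments
    mu = np.asarray(means.mu)[None, :, None]
    S = rng.normal(counts * mu, design.sigma * np.sqrt(counts))
    S[counts == 0] = 0.0
    np.cumsum(S, axis=2, out=S)
    np.cumsum(counts, axis=2, out=counts)
    return S, counts


def _z_stats(S_j, N_j, c_idx, sigma):
    """Realised-count statistics of every arm vs the per-replicate comparator."""
    rows = np.arange(S_j.shape[0])
    Sc = S_j[rows, c_idx][:, None]
    Nc = N_j[rows, c_idx][:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (S_j / N_j - Sc / Nc) / (sigma * np.sqrt(1.0 / N_j + 1.0 / Nc))
    return np.nan_to_num(Z, nan=0.0, posinf=0.0, neginf=0.0)


def run_cohort(
    design: DesignSpec,
    means: ScenarioMeans,
    n_reps: int,
    seed: int | np.random.Generator,
    *,
    policies: tuple[Policy, ...] = ("retain", "discard"),
    allocation: str = "blocked",
    futility_binding: bool = True,
    record_stats: bool = False,
    presampled_sums: np.ndarray | None = None,
) -> dict:
    """Simulate ``n_reps`` trials and apply the decision rules for every policy.

    Returns raw per-replicate outcome arrays; :func:`estimate_oc` and
    :func:`random_allocation_experiment` summarise them.  Exact statistic
    ties at the control change (probability zero for continuous responses)
    are broken towards the lowest arm index.  ``presampled_sums`` injects a
    ``(n_reps, K+1, J)`` cumulative-sum array instead of drawing responses
    (used to drive the decision rules with constructed data).
    """
    if not design.has_boundaries:
        raise ValueError("design has no boundaries; calibrate first")
    if means.K != design.K:
        raise ValueError("scenario arm count does not match design")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K, J = design.K, design.J
    if presampled_sums is not None:
        if allocation != "blocked":
            raise ValueError("presampled sums require blocked allocation")
        S = np.asarray(presampled_sums, dtype=float)
        if S.shape != (n_reps, K + 1, J):
            raise ValueError(f"presampled sums must have shape {(n_reps, K + 1, J)}")
        nj = design.n_per_stage * np.arange(1, J + 1, dtype=float)
        N = np.broadcast_to(nj, S.shape)
    elif allocation == "blocked":
        S = _cumulative_sums(design, means, n_reps, rng)
        nj = design.n_per_stage * np.arange(1, J + 1, dtype=float)
        N = np.broadcast_to(nj, S.shape)
    elif allocation == "random":
        S, N = _random_allocation_sums(design, means, n_reps, rng)
    else:
        raise ValueError(f"allocation must be 'blocked' or 'random', got {allocation!r}")

    R = n_reps
    u = np.asarray(design.upper)
    l = np.asarray(design.lower)
    rows_all = np.arange(R)

    active = np.ones((R, K + 1), bool)  # being recruited/tested or serving as control
    changed = np.zeros(R, bool)
    ck = np.zeros(R, int)  # current control arm (0 before any change)
    cj = np.zeros(R, int)  # change stage (0 = none)
    became_control = np.zeros((R, K + 1), bool)
    rejected_orig = np.zeros((R, K + 1), bool)
    pre_dropped = np.zeros((R, K + 1), bool)
    active_at_change = np.zeros((R, K + 1), bool)
    any_cross_orig = np.zeros(R, bool)
    post = {
        p: {"active": np.zeros((R, K + 1), bool),
            "rejected": np.zeros((R, K + 1), bool),
            "dropped": np.zeros((R, K + 1), bool)}
        for p in policies
    }
    z_pre_rec = np.full((R, K + 1, J), np.nan) if record_stats else None
    z_post_rec = {p: np.full((R, K + 1, J), np.nan) for p in policies} if record_stats else None

    for j in range(1, J + 1):
        i = j - 1
        pre = ~changed
        if pre.any():
            Z = _z_stats(S[:, :, i], N[:, :, i], np.zeros(R, int), design.sigma)
            test = active.copy()
            test[:, 0] = False
            test &= pre[:, None]
            if record_stats:
                z_pre_rec[:, :, i] = np.where(test, Z, z_pre_rec[:, :, i])
            Zm = np.where(test, Z, -np.inf)
            cross = Zm > u[i]
            has = cross.any(axis=1)
            any_cross_orig |= has
            # lowest-index tie break: argmax returns the first maximum
            kbest = Zm.argmax(axis=1)
            drop = test & (Z < l[i]) & ~cross
            active &= ~drop
            pre_dropped |= drop
            rows = np.where(has)[0]
            if j < J:
                ck[rows] = kbest[rows]
                cj[rows] = j
                changed[rows] = True
                active[rows, 0] = False  # original control leaves the trial
                became_control[rows, kbest[rows]] = True
                aac = active[rows].copy()
                aac[np.arange(len(rows)), kbest[rows]] = False  # control is not tested
                active_at_change[rows] = aac
                for p in policies:
                    post[p]["active"][rows] = aac
            else:
                became_control[rows, kbest[rows]] = True
                ck[rows] = kbest[rows]
                cj[rows] = J
                changed[rows] = True
                others = cross.copy()
                others[rows, kbest[rows]] = False
                rejected_orig |= others
        for p in policies:
            mask = changed & (cj < j) & (cj > 0)
            if not mask.any():
                continue
            ap = post[p]["active"]
            if p == "retain":
                Zp = _z_stats(S[:, :, i], N[:, :, i], ck, design.sigma)
            else:
                idx_change = (cj - 1).clip(0)[:, None, None]
                Sp = S[:, :, i] - np.take_along_axis(S, idx_change, axis=2)[:, :, 0]
                if allocation == "blocked":
                    Np = ((j - cj).clip(0) * design.n_per_stage)[:, None].astype(float)
                    Np = np.broadcast_to(Np, Sp.shape)
                else:
                    Np = N[:, :, i] - np.take_along_axis(N, idx_change, axis=2)[:, :, 0]
                Zp = _z_stats(Sp, Np, ck, design.sigma)
            test = ap & mask[:, None]
            if record_stats:
                z_post_rec[p][:, :, i] = np.where(test, Zp, z_post_rec[p][:, :, i])
            rej = test & (Zp > u[i])
            post[p]["rejected"] |= rej
            ap &= ~rej
            dr = test & (Zp < l[i]) & ~rej
            if futility_binding:
                ap &= ~dr
            post[p]["dropped"] |= dr

    out = {
        "changed": changed, "ck": ck, "cj": cj,
        "became_control": became_control,
        "rejected_vs_original": rejected_orig,
        "pre_dropped": pre_dropped,
        "active_at_change": active_at_change,
        "any_upper_crossing_vs_original": any_cross_orig,
        "post": post,
        "S": S, "N": np.asarray(N),
    }
    if record_stats:
        out["z_pre"] = z_pre_rec
        out["z_post"] = z_post_rec
    return out


def simulate_trial(
    design: DesignSpec,
    means: ScenarioMeans,
    policy: Policy,
    rng_state: int | np.random.Generator,
) -> TrialPath:
    """Simulate a single trial realisation and return its full path."""
    res = run_cohort(design, means, 1, rng_state, policies=(policy,), record_stats=True)
    change = None
    if res["changed"][0] and res["cj"][0] < design.J:
        change = (int(res["ck"][0]), int(res["cj"][0]))
    status: dict[int, str] = {}
    p = res["post"][policy]
    for arm in range(1, design.K + 1):
        if res["became_control"][0, arm]:
            status[arm] = _STATUS["became_control"]
        elif p["rejected"][0, arm]:
            status[arm] = _STATUS["rejected_new"]
        elif res["rejected_vs_original"][0, arm]:
            status[arm] = _STATUS["rejected_orig"]
        elif res["pre_dropped"][0, arm] or p["dropped"][0, arm]:
            status[arm] = _STATUS["dropped"]
        else:
            status[arm] = _STATUS["completed"]
    seed = rng_state if isinstance(rng_state, int) else None
    return TrialPath(
        z_pre=res["z_pre"][0],
        z_post={policy: res["z_post"][policy][0]},
        change=change,
        status={policy: status},
        seed=seed,
    )


def _binomial_se(p: float, n: int) -> float:
    return float(np.sqrt(max(p * (1.0 - p), 0.0) / n)) if n > 0 else float("nan")


def estimate_oc(
    design: DesignSpec,
    means: ScenarioMeans,
    change: ChangeConfig,
    k_star: int,
    n_reps: int,
    seed: int | np.random.Generator,
    *,
    policies: tuple[Policy, ...] = ("retain", "discard"),
    k_star_overall: int | None = None,
) -> dict[Policy, OCResult]:
    """Empirical operating characteristics with binomial standard errors.

    Conditional quantities are estimated on the replicates that realise the
    conditioning event — arm ``k_prime`` becomes control at ``j_prime`` with
    ``k_star`` still active.  Overall power counts replicates in which
    ``k_star_overall`` (default: the arm with the greatest mean) becomes the
    control or is later declared superior to the new control.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    change.validate_for(design)
    if k_star == change.k_prime:
        raise ValueError("k_star must differ from k_prime")
    if k_star_overall is None:
        effects = list(means.mu[1:])
        k_star_overall = int(np.argmax(effects)) + 1  # lowest index on ties
    res = run_cohort(design, means, n_reps, seed, policies=policies)
    cond = (
        res["changed"]
        & (res["ck"] == change.k_prime)
        & (res["cj"] == change.j_prime)
        & res["active_at_change"][:, k_star]
    )
    n_cond = int(cond.sum())
    if n_cond == 0:
        raise ValueError(
            f"no replicate realised the conditioning event in {n_reps} draws; "
            "it is too rare at this scenario — increase n_reps"
        )
    out: dict[Policy, OCResult] = {}
    for p in policies:
        rej = res["post"][p]["rejected"][:, k_star]
        cp = float(rej[cond].mean())
        found = res["became_control"][:, k_star_overall] | res["post"][p]["rejected"][:, k_star_overall]
        op = float(found.mean())
        t1 = cp if means.mu[k_star] <= means.mu[change.k_prime] else None
        out[p] = OCResult(
            policy=p,
            scenario=means,
            conditional_power=cp,
            conditional_type1=t1,
            overall_power=op,
            standard_errors={
                "conditional_power": _binomial_se(cp, n_cond),
                "overall_power": _binomial_se(op, n_reps),
                "n_conditioning": n_cond,
            },
            n_replicates=n_reps,
        )
    return out


def estimate_fwer(
    design: DesignSpec,
    n_reps: int,
    seed: int | np.random.Generator,
    *,
    futility: str = "nonbinding",
) -> tuple[float, float]:
    """Simulated FWER at the global null; returns (estimate, standard error).

    ``binding``: fraction of trials in which some arm crosses the upper
    boundary while following the futility rules.  ``nonbinding``: fraction
    in which some statistic would cross were futility stopping ignored —
    the estimand the boundary calibration targets.
    """
    means = ScenarioMeans(mu=(0.0,) * (design.K + 1))
    if futility == "binding":
        res = run_cohort(design, means, n_reps, seed, policies=())
        p = float(res["any_upper_crossing_vs_original"].mean())
    elif futility == "nonbinding":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        S = _cumulative_sums(design, means, n_reps, rng)
        nj = design.n_per_stage * np.arange(1, design.J + 1, dtype=float)
        Z = (S[:, 1:, :] - S[:, :1, :]) / (design.sigma * np.sqrt(2.0 * nj))
        p = float((Z > np.asarray(design.upper)).any(axis=(1, 2)).mean())
    else:
        raise ValueError(f"futility must be 'binding' or 'nonbinding', got {futility!r}")
    return p, _binomial_se(p, n_reps)


def random_allocation_experiment(
    design: DesignSpec,
    means: ScenarioMeans,
    n_reps: int,
    seed: int | np.random.Generator,
    *,
    k_star: int | None = None,
    allocation: str = "random",
) -> pd.DataFrame:
    """Policy discordance table under per-patient simple random allocation.

    Cross-tabulates, over replicates sharing the same patient data, whether
    the treatment of interest is taken forward (becomes control or beats the
    new control) under each data policy.  Returns a tidy table of the four
    cells with proportions and binomial standard errors.
    """
    if k_star is None:
        k_star = int(np.argmax(means.mu[1:])) + 1
    res = run_cohort(design, means, n_reps, seed, policies=("retain", "discard"),
                     allocation=allocation)
    found = {
        p: res["became_control"][:, k_star] | res["post"][p]["rejected"][:, k_star]
        for p in ("retain", "discard")
    }
    rows = []
    for r_val, d_val, label in [
        (True, True, "both"),
        (True, False, "retain_only"),
        (False, True, "discard_only"),
        (False, False, "neither"),
    ]:
        count = int(((found["retain"] == r_val) & (found["discard"] == d_val)).sum())
        prop = count / n_reps
        rows.append({
            "retain_found": r_val, "discard_found": d_val, "cell": label,
            "count": count, "proportion": prop, "se": _binomial_se(prop, n_reps),
        })
    return pd.DataFrame(rows)
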
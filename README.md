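# controlswitch

Design and operating characteristics of frequentist multi-arm multi-stage
(MAMS) **platform trials in which one experimental arm can replace the
control mid-trial**. When a treatment is declared superior it becomes the
new standard of care and the remaining arms are tested against it — either
**retaining** all data collected before the change or **discarding** it and
using only post-change data. The package quantifies what that choice costs:
it computes, exactly, the conditional power, the conditional type-I error
and the overall power of the trial under both policies, and it calibrates
the underlying group-sequential design.

It is written for trial statisticians designing or re-designing platform
trials with normally distributed endpoints and known variance.

## Model

`K` experimental arms share one control at `J` equally spaced analyses with
`n` patients per arm per stage. Arm `k` is compared with the current
control `k'` by

    Z[k,k',j] = (S_k(n_j) - S_k'(n_j)) / (sigma * sqrt(2 n_j)),   n_j = j n,

against triangular boundaries `u_j = C(1 + j/J)/sqrt(j)`,
`l_j = C(-1 + 3j/J)/sqrt(j)` whose constant `C` is calibrated so the
familywise error rate at the global null equals the nominal one-sided
level. `Z > u_j` declares superiority (the largest crosser becomes the new
control), `Z < l_j` drops the arm for futility. After a change at stage
`j'`, the discard policy replaces `Z` by the post-change statistic
`Z*[k,k',j,j'] = (post-change sums) / (sigma sqrt(2(n_j - n_j')))`.

For a watched arm `k*`, conditional power is
`P(E1∩E2∩E3∩E4)/P(E1∩E2∩E3)` (retain) or `P(E4*)` (discard), where E1-E3
condition on `k'` becoming control at `j'` with `k*` still active and E4
is the later rejection; the conditional type-I error is the same quantity
when `mu_k* <= mu_k'`. Overall power for the best arm decomposes as
`sum_j Xi[k*,j] + sum_{k',j'} Omega[k*,k',j']`. All probabilities are
exact multivariate-normal rectangle integrals (deterministic fixed-seed
quasi-Monte Carlo; the largest-crosser tie rule is handled by conditioning
on the incoming control's statistic). A patient-level simulator with
common random numbers across policies provides an independent check of
every quantity.

## Worked example

The motivating four-arm design: `K = 3` doses vs control, one interim
(`J = 2`), one-sided FWER 5%, 90% pairwise power at a standardised effect
of 0.545.

```yaml
# trial.yaml
K: 3
J: 2
n_per_stage: 43
sigma: 1.0
boundary_shape: triangular
alpha_fwer: 0.05
theta1: 0.545
power_target: 0.9
scenarios:
  - mu: [0.0, 0.5, 0.25, 0.0]
change: {k_prime: 1, j_prime: 1}
```

```
$ controlswitch design --config trial.yaml
K,J,alpha_fwer,sigma,u_1,l_1,u_2,l_2,theta1,power_target,n_per_stage,max_total_N
3,2,0.050000,1.000000,2.354243,0.784748,2.219602,2.219602,0.545000,0.900000,43,344
```

The calibrated triangular boundaries are `U = (2.354, 2.220)`,
`L = (0.785, 2.220)`; 43 patients per arm per stage (344 in total) attain
the 90% pairwise power target, and 42 do not.

```
$ controlswitch oc --config trial.yaml
policy,k_star,k_prime,j_prime,mu,cond_power,cond_t1e,overall_power,...
retain,2,1,1,0|0.5|0.25|0,0.000000,0.000000,0.796079,...
discard,2,1,1,0|0.5|0.25|0,0.000364,0.000364,0.802105,...
```

Reading: if dose 1 (true effect 0.5) is promoted to control at the
interim, dose 2 (true effect 0.25, so truly inferior to the new control)
is almost never falsely declared superior when the pre-change data are
kept (conditional type-I error below 1e-6, printed as 0.000000), but
discarding the data raises that to 0.036%; the overall probability that the best dose
is found is 79.6% retaining vs 80.2% discarding. Retaining data lowers
both the error *and* the power — the central trade-off the package
measures. `controlswitch grid` sweeps these contrasts over a whole effect
grid and reports the surface maxima; `controlswitch simulate` reproduces
any of the numbers by brute-force simulation.

## Layout

- `design_model` — design/scenario/change types, YAML-JSON configs, validation
- `joint_gaussian` — exact joint law of all test statistics; batched
  rectangle probabilities (fixed-seed QMC)
- `calibration` — triangular boundaries, FWER, pairwise power, sample size
- `operating_characteristics` — events E1-E4/E4*, conditional and overall power
- `trial_simulator` — patient-level Monte Carlo oracle, FWER and
  discordance experiments
- `grid_runner` — effect-grid surfaces and their maxima
- `cli` — `design` / `oc` / `grid` / `simulate` subcommands

See `docs/methods.md` for the full model description, numerical choices
and limitations.
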
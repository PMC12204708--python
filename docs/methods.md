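# Methods

## The trial model

`controlswitch` models a frequentist multi-arm multi-stage (MAMS) platform
trial: `K` experimental arms are compared with one shared control (arm 0)
at `J` analyses. Patient responses are independent normal with known
standard deviation `sigma`; every active arm, including the control,
recruits `n_per_stage` patients between consecutive analyses, so analyses
are equally spaced in information and the cumulative per-arm sample size at
analysis `j` is `n_j = j * n_per_stage`. Unequal allocation or unequally
spaced looks are rejected at validation rather than approximated.

At analysis `j` arm `k` is compared with the current control `k'` through

    Z[k,k',j] = (sum_{i<=n_j} X[k,i] - sum_{i<=n_j} X[k',i]) / (sigma * sqrt(2 n_j)).

If `Z > u_j` the arm is declared superior; if `Z < l_j` it is dropped for
futility; otherwise it continues. The final analysis is binding
(`l_J = u_J`). The first time an arm is declared superior it *becomes the
new control*; when several arms cross at the same analysis, the one with
the largest statistic is promoted. A single control change is modelled.
After the change, the remaining arms are tested against the new control
under one of two data policies:

* **retain** — the statistic keeps all data: `Z[k,k',j]` as above;
* **discard** — only post-change data enter:
  `Z*[k,k',j,j'] = (post-change sum difference) / (sigma * sqrt(2 (n_j - n_j')))`,
  where `j'` is the change stage.

The same boundary sequence `u_{j'+1}, ..., u_J` continues to be used under
both policies; the discard policy does not restart the boundary schedule.

## Operating characteristics

For a watched arm `k*` and a change to arm `k'` at stage `j'`, define

* E1: `k'` becomes the control at `j'`;
* E2: `k*` is still in the trial at the change (never below `l` up to and
  including `j'`);
* E3: no other arm becomes the control (nobody crosses `u` before `j'`,
  and any same-stage crosser has a smaller statistic than `k'`);
* E4 (resp. E4*): `k*` crosses `u` at some remaining analysis before
  falling below `l`, using the retained (resp. post-change-only) statistic.

**Conditional power** is `P(E1∩E2∩E3∩E4) / P(E1∩E2∩E3)` under the retain
policy; under the discard policy the post-change increments are independent
of everything observed before the change, so it is simply `P(E4*)`.
**Conditional type-I error** is the same quantity on scenarios with
`mu_{k*} <= mu_{k'}`; it is reported as undefined otherwise. **Overall
power** for the arm with the greatest true effect decomposes into `Xi`
terms (the best arm becomes the control at stage `j*`, `j* = 1..J`) and
`Omega` terms (another arm becomes control at `j' < J` and the best arm
later beats it); under the discard policy each `Omega*` factorises as
`P(E1∩E2∩E3) * P(E4*)`. `Omega` terms with `j' = J` are identically zero —
no analysis remains — and are reported as exact zeros rather than omitted.

### Event algebra

All events are decomposed into disjoint unions of axis-aligned rectangles
on a jointly Gaussian vector of statistics. Every statistic is expanded as
a coefficient vector over the independent per-arm per-stage response-sum
increments, so drifts and covariances are exact inner products and every
covariance matrix is a Gram matrix (positive semi-definite by
construction). This one expansion covers pre-change, retained and
post-change-only statistics simultaneously, e.g. it yields
`corr(Z[2,1,2], Z[2,0,1]) = sqrt(n_1/n_2)/2` and the exact independence of
`Z*` from all pre-change statistics.

The largest-crosser tie rule is the only non-rectangular constraint. All
of its inequalities compare other arms' change-stage statistics with the
*same* pivot statistic `Z[k',0,j']`, so the package conditions on the
pivot: given its value `z`, each ordering becomes an ordinary bound
(`other <= z`) and the conditional law is again Gaussian with a
value-independent covariance. The outer integral over `z` uses
Gauss-Legendre quadrature (48 nodes by default) on the pivot's truncated
range; the inner rectangle probabilities for all nodes share one Cholesky
factor and are evaluated in a single batched call. A generic fallback that
appends difference coordinates is retained for order constraints without a
shared pivot; it raises if the augmented covariance is singular (which is
exactly the situation the pivot route avoids).

An arm that crosses `u_{j'}` at the change stage without being the largest
crosser **stays in the trial** by default (`crossers_remain_active=True`):
the decision rules only promote the maximum, and the ordering theorems
need only that the watched arm was no better than the new control. The
stricter variant, in which such an arm would leave, is implemented behind
the flag and shrinks the conditioning event; the default reproduces the
motivating design's headline numbers.

### Rectangle probabilities

Rectangle probabilities are computed by a Genz-style sequential
conditioning transformation driven by a scrambled Sobol sequence with a
fixed scramble seed: results are deterministic and reproducible
bit-for-bit on a given platform. The routine is vectorised over both the
Sobol points and arbitrarily many bound-sets sharing one covariance, which
is what makes grid evaluation affordable; scipy's `multivariate_normal.cdf`
(an independent implementation of the same integral) serves as a
cross-check oracle in the test suite, alongside plain Monte Carlo. With
the default 2^13 points the absolute error on dimensions up to six is
about 1e-6-1e-7 (verified against scipy at `abseps=1e-8`); grid evaluation
uses a documented faster profile (2^11 points, 32 quadrature nodes, error
~1e-5) because the surfaces are compared on a percentage-point scale. A
region dimension cap (12) guards against runaway event constructions.

## Boundary calibration

Triangular boundaries for equally spaced analyses are

    u_j = C (1 + j/J) / sqrt(j),      l_j = C (-1 + 3 j/J) / sqrt(j),

which meet at the final analysis. `C` is found by Brent root-finding so
that the familywise error rate at the global null equals the nominal
one-sided level, to |FWER - alpha| <= 1e-6.

Two FWER conventions are implemented. The default, used for calibration,
is **non-binding futility**: the probability that any statistic exceeds its
upper boundary at any analysis, ignoring the lower boundary. This is the
standard calibration target because it guarantees the error rate even if
futility stopping is overrun in practice. The **binding** convention — an
arm below `l_j` can no longer reject — is available as an option and is
cross-checked against the simulator. For the motivating four-arm,
two-stage design at 5% one-sided the exact non-binding calibration gives
`C = 1.56950`, i.e. `U = (2.354, 2.220)`, `L = (0.785, 2.220)`. Published
tables computed with Monte Carlo integrators at their default tolerance
(around 1e-3 on the error rate) can differ from these exact values in the
third decimal; the package stores boundaries at full precision and rounds
only for display.

Calibration is performed for the pre-change trial only. No FWER guarantee
is attempted after the control change: the original boundaries were not
designed for the post-change comparisons, which is precisely why the
conditional type-I error is studied.

**Pairwise power** is the marginal probability that a single arm with true
effect `theta` crosses the upper boundary at some analysis of its two-arm
comparison with the control (drift `theta * sqrt(n_j / (2 sigma^2))`,
group-sequential correlation `sqrt(n_j/n_j')`). The sample-size search
scans integers upward from the analytic fixed-design bound
`2 sigma^2 (u_J + z_power)^2 / theta^2` per arm (spread over `J` stages)
and returns the smallest `n` meeting the target; no fractional sample
sizes. For the motivating design (`theta1 = 0.545`, 90% pairwise power)
this returns 43 patients per arm per stage, 344 in total, under either
FWER convention.

## The simulator

The patient-level simulator draws every patient response, forms the
statistics, and applies the decision rules directly; it is the independent
oracle for every analytic quantity. Design choices:

* **Common random numbers**: both policies are evaluated on the same
  response sums; they share every pre-change trajectory and differ only in
  the post-change statistics. Policy contrasts and discordance tables are
  therefore low-variance.
* Statistics are computed in realised-count form
  `(mean_k - mean_c)/(sigma sqrt(1/N_k + 1/N_c))`, identical to the
  balanced formula under block allocation and correct under random
  allocation.
* Exact statistic ties at a change (probability zero for continuous data,
  possible with constructed inputs) are broken towards the lowest arm
  index.
* A crossing at the final analysis is recorded as the crosser "becoming
  the control" for overall-power accounting (the `Xi` union runs to `J`);
  other same-analysis crossers are recorded as rejections against the
  original control and do not count towards any arm's conditional power.

The **simple-random-allocation experiment** replaces fixed blocks by
per-patient equiprobable allocation: each stage's cohort of
`n_per_stage * (K+1)` patients is allocated multinomially across the K+1
original arms, so realised per-arm stage totals vary. The randomisation
list is fixed at trial start — responses of arms that have left the trial
are simply never used — which keeps both policies on identical patient
data; allocating only among currently active arms would let the two
policies' patient streams diverge after the change and destroy the
common-random-numbers contrast the experiment exists to measure. Arm
counts of zero (vanishingly rare at realistic sample sizes) yield a
statistic treated as "continue". The experiment reports the 2x2
cross-tabulation of "treatment of interest taken forward" under
retain/discard with binomial standard errors; it is run at 1e5-1e6
replicates, which resolves the discordance *fractions* well but not rare
counts of order 1e-6.

## What the synthetic scenarios do and do not show

All evaluations use synthetic normal responses with known variance — the
model under which the method's guarantees are stated. Passing tests
demonstrate internal correctness (analytic probabilities equal the law of
the simulated trial) and reproduction of the design quantities; they do
not address model misspecification on real data: unknown or non-constant
variance, non-normal endpoints, time trends across the change, or
staggered arm entry. Those settings are outside scope.

## Numerical choices and degenerate inputs

* Quadrature/QMC defaults: 48 Gauss-Legendre nodes, 2^13 Sobol points
  (fixed scramble seed `20230545`); grid profile 32 nodes, 2^11 points.
* The pivot's integration range is truncated at 8.5 conditional standard
  deviations (mass beyond < 1e-17).
* Conditioning events with probability below 1e-12 raise a
  `ConditioningError` rather than returning a ratio of numerical noise;
  grid cells affected are flagged, not fatal.
* Tied best arms in `overall_power` raise and ask for an explicit `k_star`
  (the grid runner and simulator break ties towards the lowest index and
  say so).
* `J = 1` designs are valid (no interim, `u_1 = l_1`); change
  configurations require at least one post-change analysis (`j' < J`).
* Sample-size search requires `theta1 > 0`; boundaries are stored at full
  precision.

## Problem sizes used in the shipped analyses

The acceptance analysis calibrates the four-arm two-stage design, searches
the sample size, and evaluates a 31 x 31 scenario grid (step 0.05 on
[-0.5, 1.0]^2, third arm at the control mean) — about 90 seconds on one
CPU. Simulator cross-checks run at 1e5 replicates per scenario and the
global-null FWER check at 1e6 replicates; ordering-theorem suites use 200
randomized designs per property. These sizes give Monte Carlo standard
errors an order of magnitude below every tolerance they are checked
against.

## Known limitations

* Normal endpoints with known variance only; no t-statistics.
* One control change; no arms added after start; no concurrent-control
  bookkeeping for late entries.
* FWER conventions cover binding/non-binding futility for the pre-change
  trial; no post-change multiplicity adjustment is offered.
* The triangular family is the only built-in boundary shape (the
  calibration machinery accepts any explicit boundary vectors).
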
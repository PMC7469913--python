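# Methods

This note records the statistical conventions, numerical choices and known
limitations of the escalation engine. It is the reference for *why* the
code computes what it computes; the README shows *how* to run it.

## Dose-toxicity models and standardized doses

Three monotone families are supported. The empiric (power) model
`ψ(x, a) = x^exp(a)` and the fixed-intercept logistic
`ψ(x, a) = expit(b + exp(a)x)` have one free parameter; the two-parameter
logistic `ψ(x, a0, a1) = expit(a0 + a1 x)` with `a1 > 0` is used by the
EWOC family. Standardized doses are derived from the skeleton at the
neutral parameter value `a = 0`: for the empiric family the working dose
*is* the skeleton probability; for logistic families it is
`logit(p) − b` (resp. `logit(p)`). This makes the skeleton the single
user-facing prior object — raw milligram doses never enter the model.

## Skeleton calibration

`calibrate_skeleton(theta, delta, nu, K, model)` anchors level `nu` at the
target `theta` and places neighbours so that the parameter value mapping
level `i+1` to `theta + delta` maps level `i` to `theta − delta`: adjacent
levels straddle exactly one indifference interval. For the empiric family
this yields the closed recursion

    p_{i+1} = exp( ln(theta+delta) · ln(p_i) / ln(theta−delta) )

(and its inverse downward); logistic families are solved numerically level
by level with `brentq` at tolerance 1e−10, since no closed form exists.
With `theta = 0.2`, `delta = 0.05`, `nu = 3`, `K = 6` the empiric skeleton
is 0.049, 0.111, 0.200, 0.308, 0.423, 0.534 (3 d.p.). Very large
halfwidths (e.g. `delta/min(theta, 1−theta) ≳ 0.7` with the anchor at the
top level) drive the recursion below double-precision range and raise a
validation error rather than returning subnormal probabilities.

## Likelihood, TITE weights, and pending patients

All estimation uses the weighted binomial likelihood
`∏_j [w_j ψ]^{y_j} [1 − w_j ψ]^{1−y_j}` in log space. Weights are always
recomputed from `(u, T, outcome)` at estimation time, never cached: a DLT
has weight 1, a patient on follow-up has the linear weight `u/T`, and in
non-TITE designs every resolved patient has weight 1. A pending patient
with `u = 0` has weight 0 and contributes nothing (the weighted
likelihood's limit), but still occupies an id.

Non-TITE designs accept a pending inclusion but *defer* the model-based
recommendation until the outcome is resolved; asking for one raises
`PendingOutcomeError`. This is deliberate: without a window `T` there is
no principled partial weight.

## Posterior computation (one-parameter designs)

The posterior over `a` is computed by trapezoid quadrature on a fixed grid
of 2001 nodes spanning the prior mean ± 8 prior standard deviations
(clipped to the support for bounded/positive priors), with the
prior × likelihood product evaluated in log space and normalized by the
trapezoid marginal. The grid is deterministic, so identical histories give
bit-identical posteriors — the property behind the replay-determinism and
TITE-reduction guarantees. Truncation at ±8 sd leaves ≤ ~1e−3 of prior
mass in the heaviest supported tail (lognormal) and far less for the
default normal prior.

Per-level DLT estimates come in two modes. `plugin` (the default)
evaluates `ψ(x_i, â)` at the posterior mean `â = E[a | data]`, the
convention of the classic CRM software; `integrated` computes
`E[ψ(x_i, a) | data]` by quadrature. Both are strictly increasing across
levels; they differ for skewed posteriors (Jensen), and the recommended
dose can differ by one level early in a trial.

### The default prior

The default parameter prior for CRMB/TITE-CRM is normal with mean 0 and
**standard deviation 1.34** on `a`. The number 1.34 circulates in the CRM
literature in two incompatible parameterisations (as a variance,
sd ≈ 1.158, and as an sd); this engine's reference operating
characteristics — the 1000-trial simulation reproduced by
`scripts/acceptance.py` and the acceptance tests — were matched under the
sd convention, which gives a slightly less informative prior and faster
adaptation, and it is therefore the default. The variance convention is
one line away: `PriorSpec("normal", (0.0, 1.34))`. The classic
unit-exponential prior `f(a) = e^{−a}` is also available.

## Dose selection and constraints

CRM designs recommend `argmin_i |ψ̂_i − θ|` with ties broken to the lower
(safer) level; a tolerance of 1e−12 on the distance comparison makes the
tie-break robust to float representation (0.15 vs 0.25 at θ = 0.2 breaks
down). The no-skip constraint — on by default for every design — caps any
recommendation at one level above the highest level tried so far. The
maximum-likelihood variant (CRML) requires at least one DLT and one
non-DLT before the likelihood has a maximiser; until then a run-in policy
escalates one level per DLT-free patient from the start level (cohorts of
3 and de-escalation after a DLT are configurable), then hands off to
MLE-based selection. The MLE itself is a bounded scalar optimisation on
`a ∈ [−10, 10]` (xatol 1e−9), checked in the tests against a 1e−4-step
grid search.

## EWOC

The two-parameter logistic model is reparameterised as
`ρ0 = ψ(x_1)` (DLT probability at the lowest dose) and `γ` (the MTD, the
dose with `ψ(γ) = θ`), so that `a1 > 0` becomes `ρ0 < θ, γ > x_1`.
Default priors are independent uniforms `ρ0 ~ U(0, θ)`, `γ ~ U(x_1, x_K)`;
gamma/lognormal alternatives can be supplied per coordinate. The joint
posterior is evaluated on a fixed 201 × 201 trapezoid grid. Node
placement matters more than node count here: the likelihood has boundary
layers at `ρ0 → 0` and `ρ0 → θ`, so the ρ0 nodes are placed on the logit
scale (`ρ0 = θ·expit(t)`, `t` uniform on [−25, 25]); the γ grid is
uniform, open at the singular edge `γ = x_1`. With this placement the
γ-marginal CDF agrees with 10⁶-draw Monte-Carlo oracles to ~1e−4–3e−4,
versus ~2e−3 for uniformly spaced ρ0 nodes.

The recommendation is the highest level with
`π(x) = P(MTD ≤ x | data) ≤ α` (level 1 if none qualifies), with the
no-skip cap applied afterwards. `α` is held fixed over the trial. One
structural consequence of the reparameterisation worth knowing: an
outcome at the *lowest* dose informs only `ρ0` (since `ψ(x_1) ≡ ρ0`), so
with independent priors it leaves the MTD marginal unchanged; outcomes at
any higher dose move it.

## Trial conduct

A `Trial` freezes its configuration at the first inclusion, keeps an
append-only audit log (ISO-8601 UTC timestamps), permits audited clinician
overrides of the recommended level, and persists to a single
schema-versioned JSON document via atomic write-then-rename. After any
correction (`modify_patient`) the whole recommendation sequence is
recomputed from the raw history, and the stored sequence always equals a
from-scratch replay — reloading a saved trial can never change a
recommendation. Stopping rules: maximum sample size, and "m patients
already treated at the level about to be recommended" (a fixed level may
be given instead; the recommended-level reading is the default). Batch
inclusion validates every row before applying any (atomicity) and is
restricted to TITE designs, which are the setting it exists for.

## Simulation

`run_batch` draws one substream per replicate from a root `SeedSequence`,
so results are independent of execution order and reproducible from the
root seed. Non-TITE trials resolve each outcome before the next
enrollment (staggered accrual); each patient is treated at the current
recommendation and the final recommendation after the last outcome is the
trial's MTD — computed by the same `recommend()` path as live conduct,
no-skip cap included. TITE trials enroll on a fixed accrual clock
(default inter-arrival `T/3`, three patients per window); given a DLT, its
onset time is uniform on `(0, T]`; at each enrollment earlier patients
enter the likelihood with their elapsed-time weights, and the final
analysis uses complete follow-up.

Reported operating characteristics: the per-level MTD recommendation
distribution with binomial standard errors, mean per-level allocation with
empirical standard errors, mean DLT count, and the average fractions of
patients treated below/at/above the *true* MTD (the level whose true DLT
probability is closest to the target). Percentages are displayed to one
decimal; raw values are kept at full precision.

## Problem sizes used by the tests

The acceptance checks run the reference scenario at its stated size
(1000 trials × 25 patients, both CRMB and EWOC) and drive the Monte-Carlo
oracles at 10⁶ draws over ≥ 20 random histories. Statistical properties
of the simulator itself (substream independence, SE scaling) use a
reduced 4-level design with 8-patient trials and a 201-node parameter
grid so the whole suite stays fast; nothing in those properties depends
on problem size.

## Known limitations

- Only the linear TITE weight is implemented; adaptive weights are out of
  scope by design.
- One-parameter posteriors use fixed-grid quadrature, not MCMC; this is a
  feature (determinism) but limits the engine to the model families above.
- The EWOC feasibility bound is constant over the trial; the
  increasing-α variant is not implemented.
- Simulated accrual is deterministic (fixed inter-arrival); random accrual
  processes are not modelled.
- The simulator is single-process; determinism takes priority over
  parallel throughput.
- Scenario truths are per-level Bernoulli probabilities; the simulator
  does not model within-patient dose modifications or competing risks.
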
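# dosefind

Model-guided dose escalation for phase I oncology trials: the continual
reassessment method with Bayesian (CRMB) or maximum-likelihood (CRML)
estimation, its time-to-event extension (TITE-CRM), escalation with
overdose control (EWOC) and TITE-EWOC — as an importable library with a
thin command-line interface, covering both the *conduct* of a real trial
(inclusions, pending outcomes, audit trail, persistence) and the
*simulation* of a design's operating characteristics before the protocol
is written.

It is aimed at trial statisticians who want the escalation engine behind a
protocol to be scriptable, reproducible and auditable.

## The models

A trial has `K` dose levels with standardized doses `x_1 < … < x_K`, a
target toxicity level `θ` (the acceptable probability of dose-limiting
toxicity, DLT), and a skeleton `p_1 < … < p_K` of prior DLT probabilities.
Patient `j` treated at dose `x` has `Y_j ~ Bernoulli(ψ(x, a))` with a
monotone dose-toxicity model:

- empiric (power): `ψ(x, a) = x^exp(a)`, `x ∈ (0,1)`;
- one-parameter logistic: `ψ(x, a) = expit(b + exp(a)·x)` with fixed
  intercept `b` (default 3);
- two-parameter logistic (EWOC): `ψ(x, a0, a1) = expit(a0 + a1·x)`,
  `a1 > 0`.

All estimation runs through the weighted likelihood
`L(a) = ∏_j [w_j ψ(x_j,a)]^{y_j} [1 − w_j ψ(x_j,a)]^{1−y_j}`,
where `w_j = 1` for fully observed patients and `w_j = u_j/T` for a
patient followed `u_j` out of the observation window `T` without DLT (the
linear TITE weight; a DLT always has weight 1). CRM designs assign the
next patient the level whose estimated DLT probability is closest to `θ`;
EWOC designs reparameterise the logistic model as (ρ0, γ) — the DLT
probability at the lowest dose and the MTD — and assign the highest level
`x` with `P(MTD ≤ x | data) ≤ α`, the feasibility bound.

## Worked example

Calibrate the six-level skeleton used throughout the examples (target 20%
anchored at level 3, indifference halfwidth 0.05):

```
$ dosefind calibrate --target 0.2 --halfwidth 0.05 --nu 3 --levels 6
1	0.049092
2	0.110528
3	0.200000
4	0.308487
5	0.423416
6	0.533661
```

Level 3 sits exactly at the 20% target; the six values (0.049, 0.111,
0.200, 0.308, 0.423, 0.534 to three decimals) are the prior DLT
probabilities per level. Conducting a CRMB trial from Python
(`examples/conduct_crmb_trial.py`):

```
first patient treated at level 3
patient  1: level 3, DLT=0 -> next recommended level 4
patient  2: level 4, DLT=0 -> next recommended level 5
patient  3: level 5, DLT=0 -> next recommended level 6
patient  4: level 6, DLT=0 -> next recommended level 6
patient  5: level 6, DLT=1 -> next recommended level 5
patient  6: level 5, DLT=0 -> next recommended level 5
```

Clean outcomes escalate one level at a time (dose skipping is disallowed
by default); the DLT at level 6 pulls the posterior up and the
recommendation back to level 5. Simulating 200 trials of 25 patients under
an assumed truth where level 5 is the real MTD
(`examples/simulate_operating_characteristics.py`):

```
 dose_level  mtd_pct  avg_patients
          1      0.0         0.315
          2      0.0         0.580
          3      3.0         2.910
          4     27.0         6.780
          5     46.0         7.325
          6     24.0         7.090
```

`mtd_pct` is the share of trials whose final recommendation lands on each
level — the design finds the true MTD (level 5) most often — and
`avg_patients` is the mean allocation per level. The same run reports the
fraction of patients treated above the true MTD (`pct_over`), which is the
quantity EWOC is built to control: under the identical scenario an EWOC
design with `α = 0.25` keeps it near zero.

The other examples show TITE conduct with pending patients
(`examples/tite_crm_pending_patients.py`) and the EWOC overdose-control
curve (`examples/ewoc_overdose_control.py`). The `dosefind` CLI exposes
the same workflow from a shell: `calibrate`, `init`, `include`, `update`,
`modify`, `next-dose`, `summary`, `export`, `simulate`.

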
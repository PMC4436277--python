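# Methods

## Model structure

Five mutually exclusive health states: *post treatment*, *local recurrence*,
*metastasis*, *death from disease*, *death from other causes*. All patients
enter in post treatment at age 59 and are followed for five one-year cycles.
Permitted transitions:

- post treatment → local recurrence, metastasis, death (other), or stay;
- local recurrence → metastasis, death (other), or stay (no recovery to
  post treatment);
- metastasis → death (disease) with probability 1 after exactly one cycle
  (a tunnel state reflecting the short survival of metastatic uveal
  melanoma);
- both death states are absorbing.

Competing risks within a cycle are simultaneous — one multinomial draw per
patient-cycle — and the stay probability is the residual
1 − (event probabilities + background mortality). Configurations with a
negative residual are rejected, not renormalized. Background (other-cause)
mortality is applied in post treatment and local recurrence but **not** in
metastasis; under this rule the identity
*ever-metastasis = ending-metastasis + death-from-disease* holds exactly,
which the summary statistics exploit and the tests assert. Patients entering
metastasis in the final cycle end the simulation there (their death is not
"finished" beyond the horizon).

## Parameters

All defaults live in `uvealcea.params.default_parameters()` and the packaged
`data/default_parameters.yaml` (identical by test). Annual transition
probabilities per arm (base, with low–high sensitivity ranges shared across
arms): post→LR 0.002/0.021/0.009 and post→met 0.047/0.029/0.039 for
enucleation/plaque/proton; LR→met 0.074/0.045/0.061, consistent with a
relative risk of ≈1.5 versus post→met (the helper
`apply_relative_risk` documents the derivation; the stored values are the
pooled published estimates, which round slightly differently).

Costs are one-time state-entry payments in 2011 USD: treatment 8,678 /
18,222 / 12,438; local recurrence 8,678 (salvage enucleation after plaque or
proton, a radiotherapy proxy after enucleation — same figure); end-of-life
76,645 (disease, final-six-months terminal-care estimate) and 42,787 (other
causes). The plaque treatment cost is the sum of its hospital (16,444) and
physician (1,778) components; an inflation-adjusted total of 19,108 is
carried in bundle metadata and is the basis of that arm's sensitivity range
(0.70×/1.54× Medicare spending-per-beneficiary scaling, giving
13,376–29,426). Utilities: post treatment 0.71/0.71/0.706, local recurrence
0.52, metastasis 0.23 (ranges ±0.05).

Background mortality: `data/us_life_2008_59_63.csv`, 2008 US
total-population annual death probabilities q(59)–q(63)
(0.008480–0.011132). Lookups past the table clamp to the last entry; the
horizon is short enough that no extrapolation is warranted. Age advances one
year per cycle; cycle *t* uses q(59 + t).

## Accrual conventions

- **Half-cycle correction** (default on): transitions are assumed to occur
  mid-cycle. Cycle-*t* state membership is the mean of start- and
  end-of-cycle occupancy (trapezoid), used for QALYs and time-in-state.
- **Discounting** at 3 %/year: cycle-*t* membership rewards and entry events
  carry the factor (1+r)^−(t+0.5), i.e. they are valued at the mid-cycle
  time, consistent with the mid-cycle transition assumption. The initial
  treatment cost is paid at time 0, undiscounted. `ModelConfig.cost_timing`
  exposes cycle-start/cycle-end alternatives; with `half_cycle=False`
  rewards revert to start-of-cycle occupancy discounted at (1+r)^−t. The
  mid-cycle defaults were chosen as the internally consistent realization of
  the half-cycle assumption.
- **Entry costs are events, not memberships**: they are discounted but not
  trapezoid-averaged, and are paid at most once per state (re-entry is
  impossible by construction).
- Time-in-state and total life-years are undiscounted half-cycle-corrected
  occupancy sums over the three alive states.

## Engines

The **cohort** engine iterates the occupancy row vector against the 5×5
cycle transition matrix — the exact expectation of the stochastic process —
and is used wherever determinism matters (sensitivity analysis, the
deterministic acceptance checks). The **microsimulation** engine draws
individual trajectories (inverse-CDF multinomial per patient-cycle,
vectorized over the cohort), defaulting to 10,000 patients × 1,000
replications. Point estimates are means of per-replication cohort means;
95 % intervals are the 2.5/97.5 percentiles of the across-replication
distribution (a normal approximation is available via
`interval_method="normal"`; the percentile default makes no shape
assumption). Replication streams are spawned deterministically from the
root seed (`numpy` `SeedSequence`), so results are reproducible and
independent of execution order. Because both engines share the accrual
code, microsimulation estimates converge to the cohort values as
replications × cohort size grows; tests assert agreement within three
standard errors.

## CEA and dominance

ICERs are computed at full precision and rounded to the nearest $100 only at
the reporting layer. Classification is exhaustive and mutually exclusive:
numeric ICER (deltas share a sign, QALY delta nonzero), *dominant*
(≤ cost, ≥ QALYs, one strict), *dominated* (the converse), *equivalent*
(both deltas zero). At the threshold (default $50,000/QALY) a more-costly,
more-effective comparator is cost-effective iff ICER ≤ threshold (equality
counts as cost-effective); a cheaper, less-effective one iff
ICER ≥ threshold.

## One-way sensitivity analysis

The registry holds 21 parameters: 9 probabilities (3 per arm, each varied
over the shared treatment-agnostic range — LR 0.001–0.030, met 0.001–0.083,
LR→met 0.001–0.202), 7 costs (3 treatment costs over their own ranges, the
shared local-recurrence cost varied separately for enucleation versus
plaque + proton jointly, and 2 end-of-life costs), and 5 utilities (3
post-treatment, shared LR and metastasis utilities). Each extreme re-runs
**all three arms** with the cohort engine — a shared parameter legitimately
moves the reference arm — giving an 84-cell grid. The cohort engine is used
rather than microsimulation so the grid carries no Monte-Carlo noise.

A parameter is flagged *sensitive* when, at either extreme, the optimal
strategy at the threshold changes or any dominance relation against
enucleation appears. Under the default registry this yields 13 sensitive and
8 insensitive parameters. `tornado_ordering` ranks parameters by the
absolute ICER swing across their range, mapping Dominates/Dominated cells to
∓∞ so dominance-straddling parameters rank first; ties keep registry order.

## Synthetic data

`uvealcea.synthetic` generates random valid inputs for property testing and
pipeline rehearsal: probabilities uniform within the tabulated sensitivity
ranges, costs log-uniform (the ranges span ×2.2, so a log draw keeps mass
away from the extremes symmetrically in ratio terms), utilities uniform with
u_post ≥ u_LR ≥ u_met enforced, and per-arm LR→met ≥ post→met. Synthetic
mortality is Gompertz, q(age) = min(1, b·e^{c(age−59)}), b = 0.009,
c = 0.09 — the simplest monotone adult-mortality shape. Draws are
rejection-sampled until validation passes, so every generated (bundle, life
table) pair runs. The generator emulates the *structure* of the parameter
tables, not the covariances of the underlying literature: passing property
tests demonstrates engine correctness across the plausible parameter space,
not clinical realism of any particular draw.

## Numerical and degenerate cases

Occupancy rows are conserved to 1e−12 per cycle (asserted). Cumulative
sampling rows are clamped so float round-off cannot drop a patient. Zero
discount rates, zero event probabilities, and forced chains (probability-1
transitions) are exercised in tests as closed-form oracles. Monetary values
are kept at full float precision internally and rounded to whole dollars
(ICERs to $100) only in reports.

## Limitations

- Treatment-specific transition probabilities come from non-randomized,
  partially overlapping study pools; tumor size/location confounding between
  treatment choice and prognosis is not modeled (the treatment-agnostic
  sensitivity ranges are the mitigation).
- The five-year horizon stops before most late recurrences; no
  extrapolation beyond it is attempted.
- End-of-life disease cost covers the final six months only, understating
  final-year cost.
- The model has no probabilistic (distribution-sampling) sensitivity
  analysis, efficiency frontier, or net-monetary-benefit layer; the one-way
  grid is the uncertainty analysis implemented.
- The 2008 life-table fixture is total-population; sex-specific variants can
  be swapped in via `--life-table`.
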
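# Methods

## Model structure and assumptions

The package implements a deterministic state-transition (Markov) cohort
model over an ordered treatment pathway. States are mutually exclusive:
one per treatment line, one surgical state, one absorbing death state.
Each cycle a patient either stays on the current treatment (responds) or
escalates to the next line with a fixed per-cycle probability; backward
transitions are structurally impossible (the matrix is upper triangular
in pathway order), matching the clinical assumption that once a therapy
has failed it is not retried. Transition probabilities, costs and
utilities are constant over time; adverse events are not modelled as
separate states.

The surgical state escalates to death with its own per-cycle
probability, and the simulation is truncated at the cohort's average
life expectancy. No other background mortality is applied: the
remaining life-table detail is deliberately absorbed into horizon
truncation (accrual simply stops at the horizon), which for a lifetime
model with a single open cohort is equivalent to flushing all survivors
to death at the final cycle — no accrued cost or QALY differs between
the two bookkeepings, so the simpler one is used.

## Accrual conventions

Costs and QALYs accrue at **cycle end** by default: cycle *t* uses
occupancy row *t* and discount factor $(1+r)^{-t\ell}$. A half-cycle
correction is available as an explicit flag and replaces row *t* by the
trapezoidal average of rows *t−1* and *t*, approximating mid-cycle
transitions; the discount factor is unchanged. Neither convention is
privileged by the source inputs, so the simplest is the default and the
other is one keyword away. The person-time helper (`time_in_state`)
uses the identical conventions so that a utility-1, zero-discount run
reduces exactly to person-years.

Horizon rounding is `ceil`: a fractional final cycle is modelled as a
whole cycle (conservative, documented). Rows within 1e-8 of stochastic
are renormalised with a logged warning on input; anything worse is a
hard error. Validation proper demands row sums within 1e-12.

## Parameters of the bundled input set

Six-month cycles from age 40 to the 2021 Vietnamese average life
expectancy of 73.6 years (68 cycles); 3%/year discount on costs and
outcomes; 2021 GDP per capita of USD 3756 at 23,486 VND/USD, i.e.
88,213,416 VND, defining willingness-to-pay thresholds at 1× and 3× GDP
per QALY (boundary values fall in the middle band, since the verbal rule
"below 1× / between 1× and 3× / above 3×" leaves them formally
uncovered; this is configurable in code).

Per-cycle escalation probabilities, per-cycle costs (VND) and utilities
per state, from the Vietnamese drug tariff and published trials:

| state            | escalation | direct medical | utility |
|------------------|-----------:|---------------:|--------:|
| acetaminophen    | 0.3380     | 588,600        | 0.7010  |
| glucosamine      | 0.3857     | 186,300        | 0.6760  |
| diclofenac + PPI | 0.8647     | 60,210 + 344,700 (omeprazole) | 0.7230 |
| etoricoxib       | 0.5657     | 785,700        | 0.7230  |
| triamcinolone    | 0.0392     | 19,400         | 0.6400  |
| TKA (surgery)    | 0.5122     | 88,712,500     | 0.7600  |

The dose annotations behind the tariffed drug costs (e.g. 588,600 VND
for ~1080 acetaminophen tablets) confirm they are per 6-month cycle, so
they are used as printed; a cost-period multiplier and a
per-administration option for the triamcinolone injection (two 3-monthly
doses per cycle, i.e. 38,800 VND) are exposed for scenario analyses.
Direct non-medical costs (food 2,700,000 + transport 2,953,620 VND/month)
and absenteeism (7,342,373 VND/month) attach to the one-month
post-surgery recovery, hence to the surgical state. The bundled
absenteeism figure is a literature value and intentionally differs
slightly from the monthly-GDP method (`indirect_cost`, 88,213,416/12 =
7,351,118 VND/month) provided for synthetic scenarios.

Trial response probabilities can be converted to per-cycle escalation
probabilities by a constant-hazard transform,
$p_\text{cycle} = 1-(1-p)^{\ell/d}$ for trial duration *d*
(`efficacy_to_transition`); the bundled probabilities are interpreted as
already per-cycle because source trial durations are not part of the
input set.

## Incremental analysis

ICERs are reported as numbers only in the quadrants where the ratio is
meaningful: more costly and more effective (cost per QALY gained) and —
flagged — cheaper and less effective (savings per QALY forgone). The
other quadrants resolve to `dominant` / `dominated` / `undefined`
labels, with the raw deltas always reported; this avoids the classic
misleading-negative-ICER trap. All monetary arithmetic is double
precision VND; rounding (whole VND half-up, two-decimal USD) happens
only when report tables are serialized.

On the bundled inputs the four glucosamine add-on comparisons (PGD/PD,
PDG/PD, PGDE/PDE, PDEG/PDE) come out **dominant**: the adjunct's own
cost (~0.5M VND discounted) is smaller than the discounting-plus-
truncation saving from delaying the 88.7M-VND arthroplasty stream
(~5M VND at 3%; the sign is unchanged at 0% or 6% discount, with the
half-cycle correction, and under the alternative cost-period readings).
The add-on arms also gain ~0.55 QALYs. The reference totals bundled in
`published_base_case()` come from a different, coarser aggregation whose
per-person QALY magnitudes are not reproducible by a closed-cohort
trace; they are retained as *inputs* to the incremental-analysis layer,
which reproduces their published pairwise ICERs to printed precision.

## One-way sensitivity

The tornado routine perturbs one scalar input at a time (default set:
drug cost and utility of every state in either compared regimen,
±20%, clamped to the parameter's domain and logged), re-runs the full
pipeline at the low and high value with everything else at base, and
ranks parameters by ICER spread (ties broken lexicographically). A
perturbation that flips the comparison into a dominance quadrant records
the label in place of a number and the spread falls back to the single
numeric excursion, flagged. The tornado requires a numeric base-case
ICER; for dominant base cases the CLI reports the label and skips the
pair. The discount rate is eligible as a parameter but excluded from
the default set, which mirrors the cost/utility families.

## Synthetic scenario generator

`random_model` draws pathway instances with 2–8 pre-death states:
escalation probabilities and utilities uniform in configurable
sub-intervals, costs log-uniform one decade around a magnitude knob, an
always-absorbing death state. It emulates the *structure* of the real
problem (ordering, stochasticity, cost classes), not Vietnamese
epidemiology: passing property tests demonstrates engine correctness
(mass conservation, matrix-power equivalence, monotonicity of the
pipeline in costs and utilities), not clinical validity. A single
integer seed drives one explicit `numpy` Generator. `paired_variant`
inserts one state into an existing instance without touching the
others, mirroring the before/after adjunct construction.

## Problem sizes and numerical choices

Default analyses run 68 half-year cycles over ≤7 states — microseconds
per strategy — so the test suite sweeps 1000 random instances and the
acceptance script re-runs everything from scratch in under a second.
Tolerances: 1e-12 row-stochasticity (1e-8 renormalisation band on
input), 1e-9 mass conservation, 1e-10 against the matrix-power oracle.
Degenerate inputs are resolved explicitly: escalation 0 yields identity
rows (valid — chain validity does not require a path to absorption);
response probability 1 maps to per-cycle probability 1 (logged);
equal-total strategies compare as `undefined`.

## Known limitations

Single closed cohort; no probabilistic sensitivity analysis, no
time-varying matrices or tunnel states, no individual-level simulation,
no sex stratification, no adverse-event states. The WTP classification
implements a GDP-multiple rule specific to the Vietnamese HTA context.
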
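# Methods

## Model

The bundled model is a single-decision tree with two strategies for chronic
anterior cruciate ligament (ACL) injury, evaluated over one 18-month horizon
from a societal perspective:

- **Early ACLR** — immediate surgical reconstruction followed by
  post-operative rehabilitation (2 visits/week for 36 weeks). Chance branches
  cover additional meniscus surgery, ACL revision (a second reconstruction),
  other surgery (manipulation under anaesthesia, hardware removal, basic
  arthroscopy), or no further surgery.
- **Conservative treatment** — structured rehabilitation. Chance branches
  cover meniscus arthroscopy without reconstruction, delayed ACLR (41%
  crossover over 18 months, with the same post-operative rehabilitation
  block), or a stable knee with rehabilitation alone.

All patients survive the horizon and end in a stable state; there are no
repeated cycles, mortality states, or age dependence. Terminal payoffs are
a total cost (US$) and a utility weight (EQ-5D-3L scale, 0–1). Branch
probabilities and payoffs are arithmetic expressions over named parameters
(literals, parameter names, `+ − * /`, parentheses, and a `complement`
keyword allowed on at most one branch per chance node, resolved as one minus
the sum of its siblings). Chance-node probabilities must sum to one within
1e−9 — a pure floating-point guard that does not mask modelling errors.

## Effectiveness accounting

The reported arm-level QALYs (0.81 and 0.86) equal the stable-state utility
weights themselves, not a 1.5-year time integral (which would be ≈1.2
undiscounted). The engine therefore defaults to
`effectiveness_mode = "utility_at_horizon"`: the QALY outcome of a path is
its terminal utility, and no discounting is applied to effects. A documented
alternative, `"time_integrated"`, reports the continuously discounted
integral `u · (1 − (1+r)^−H) / ln(1+r)` over the horizon of `H` years at
annual rate `r` (reducing exactly to `u·H` when `r = 0`). Costs are treated
as point totals per arm; the settings carry the conventional 3%/year rate
for the discounting modes that use it.

## Parameters

Base values printed in the source material are fixed: delayed-ACLR
probability 0.41; stable-knee utilities 0.86 (post-ACLR) and 0.81
(conservative); baseline utility 0.61 (context only, not a payoff); direct
ACLR cost US$2,853; rehabilitation schedule 2 × 36 visits; willingness-to-pay
US$12,876/QALY (3 × the 2021 Indonesian GDP per capita of US$4,292).

Sub-branch quantities with no published value are named free parameters with
placeholder defaults, flagged `note: assumed` in the shipped configuration:
re-operation probabilities (meniscus 0.08, revision 0.05, other 0.05 in
0–0.1, arthroscopy-without-ACLR 0.10) and sub-costs (meniscus surgery
US$800, other surgery US$500, physiotherapy visit US$15). These placeholders
are order-of-magnitude choices; the calibration below absorbs whatever they
miss into the per-arm residuals, so the arm-level results never depend on
them, only the decomposition across branches does.

Deterministic-sensitivity ranges: costs ±20% of base; probabilities get
plausible absolute ranges (delayed ACLR 0.30–0.50, spanning the ~50%
crossover discussed for longer horizons); utilities ±0.02, reflecting the
precision of a cohort-mean EQ-5D value (the published analysis found the
decision insensitive to post-treatment quality of life, which is only
consistent with narrow plausible utility ranges); calibrated residual
decrements 0–0.05. A parameter declaring no range falls back to ±20% of base
clipped to its kind bounds when a tornado is run without explicit ranges.

## Calibration

Expected values are linear in terminal payoffs, so arm-level targets pin down
free payoffs by a linear solve. Per strategy the model exposes:

- a **residual arm cost** (`c_base_aclr`, `c_base_conserv`) added to every
  terminal of the arm — it collects rehabilitation and indirect costs (salary
  loss, transportation), which are only recoverable as totals; and
- a **residual utility decrement** (`du_reop_aclr`, `du_reop_conserv`)
  subtracted on re-operation branches.

Each free value is recovered from two arm evaluations (intercept and slope)
and verified by re-evaluation to 1e−9; solutions violating kind bounds
(negative cost, decrement outside [0, 1]) or producing an out-of-bounds
terminal payoff raise a calibration error naming the offending value. With
the published arm targets the decrements solve to exactly zero — consistent
with arm QALYs that equal the stable-state utilities — and the cost residuals
come out at ≈US$101 (ACLR arm) and ≈US$1,597 (conservative arm). Solved
parameters get a refreshed ±20% plausible range around the solution. All
probabilities stay fixed during calibration: the system stays well-posed and
no probabilities are invented.

## Probabilistic sensitivity analysis

Families follow the standard convention for cost-effectiveness PSA: beta for
probabilities and utilities, gamma for costs, both parameterised by
method-of-moments from (mean, se); uniform (mean ± √3·se) is available; counts
and the zero-valued residual decrements are fixed. Default spreads when no
published value exists: se = 20% of the mean for costs and 10% of the mean
for probabilities/utilities (clipped below the beta feasibility bound
se² < m(1−m)). Distributions are **mean-centered** on base values, so the
PSA cloud mean reproduces the base case up to Monte Carlo error while
medians shift slightly with each family's skew; the acceptability-curve
checks tolerate that gap.

One seeded `numpy` generator drives everything; parameters are sampled in
sorted-name order so results are independent of configuration-file ordering,
and identical seeds give bit-identical sample sets. Sampled vectors that fail
validation (e.g. explicit probabilities on one chance node leaving a negative
complement) are rejected and resampled, with the rejection count logged and
reported.

CEAC probabilities are the fraction of draws where a strategy attains the
strictly highest NMB, with tied draws split equally so the probabilities sum
to one exactly. The CE-plane ellipse is the bivariate-normal fit to the
incremental (Δeffect, Δcost) cloud: semi-axes √(χ²₂(level)·eigenvalues) of
the sample covariance along its eigenvectors. Fewer than 3 draws yield no
ellipse; a zero-variance cloud degenerates to a point with a warning.

## Deterministic sensitivity analysis

One-way, two-way, tornado and threshold analyses share a single evaluation
core, so tornado bar endpoints are bit-identical to the corresponding one-way
evaluations. Reference/comparator roles are fixed at the base case (cheapest
strategy is the reference). The default tornado output is the **NMB
difference** (comparator − reference) at the configured willingness-to-pay:
unlike the ICER it stays well-behaved when the effect difference crosses
zero; ICER, comparator cost and comparator effect are optional outputs (an
ICER that degenerates to a dominance flag is reported as NaN). Ties in spread
break alphabetically for determinism. Threshold solving is plain bisection to
a relative output tolerance of 1e−8 (at most 200 iterations); a bracket
without a sign change returns `converged = false` with the diagnostic output
values at both ends rather than a threshold.

Under the shipped ranges the three widest tornado bars are the conservative
arm's residual cost, the direct ACLR cost and the delayed-ACLR probability,
with both utilities ranking below them — the qualitative pattern reported for
this decision problem. Note the "cost of ACLR" bar reflects the direct
surgical cost, which enters both arms (revision and delayed ACLR branches);
a bundled arm-cost interpretation is available by varying `c_base_aclr`
instead.

## What the synthetic calibration does and does not show

The calibrated model reproduces the published arm-level accounting
identically, and everything derived from arm-level outcomes (ICER, NMB,
decision rule, utility threshold, CEAC shape under the default spreads) is
therefore a genuine recomputation. What it cannot reproduce are quantities
that depend on the unpublished per-branch values and distribution spreads:
the exact 64% acceptability at US$12,876, the cost-parameter thresholds
US$3,635.15 / US$1,828.42, and the >50% delayed-ACLR crossover threshold.
Those are covered qualitatively (curve shapes, monotonicity, ranking) rather
than numerically. Passing tests validate the arithmetic and the statistical
machinery at the study's scale (5,000 draws); they do not validate the
clinical inputs themselves, which come from a single-centre cohort and one
trial's re-operation rates.

## Numerical choices

- Double precision throughout; no intermediate rounding. Display rounding
  (US$ to 2 decimals, QALYs to 6) is applied only in the human-facing CEA
  table; machine outputs keep full precision and round-trip exactly.
- Probability sum tolerance 1e−9; calibration tolerance 1e−9; rollback vs
  path-enumeration agreement tested at 1e−12.
- `decide` treats NMBs within 1e−9 (relative) as tied and returns the cheaper
  strategy with a tie flag.
- Problem sizes in the test suite: 200 random trees (depth ≤ 5, branching
  ≤ 4) for the oracle sweep, 10⁴ random instances for the decision-rule
  equivalence, 5,000 PSA draws and 10⁴-point clouds for the stochastic
  checks — the sizes the analyses themselves use.

## Known limitations

- Single-horizon tree only: no Markov cycles, half-cycle correction,
  patient-level microsimulation or heterogeneity.
- Parameters are sampled independently; no correlation structure or copulas.
- Extended-dominance handling for more than two strategies is a simple
  sorted-by-cost sweep and is flagged experimental.
- The expression language has no conditionals by design, keeping
  configurations auditable.
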
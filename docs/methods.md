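# Methods

## Model structure

The model is a time-inhomogeneous Markov cohort simulation of disease
progression after curative resection of stage III colon cancer. A
cohort enters disease-free at age 60 and is pushed forward in 1-month
cycles for 300 months (to age 85). States:

* **disease-free** — free of recurrence; implicitly indexed by model
  month (recurrence and background-mortality probabilities are
  month-specific). Patients disease-free beyond month 96 are treated as
  cured: their recurrence probability is exactly zero thereafter.
* **recurrence** — clinical distant metastasis, stratified by timing of
  recurrence (early: months ≤ 24; mid: 25–36; late: > 36; boundary
  months fall in the earlier stratum) and expanded into tunnel states
  by months already spent in recurrence (default depth 60, the deepest
  tunnel self-looping for both transitions and mortality lookup —
  post-recurrence survival conditioning flattens after about five
  years, and the depth is configurable).
* **death from colon cancer** and **death from other causes** — the two
  absorbing states.

Within a cycle, competing exits are combined on the rate scale: each
monthly probability is converted to a rate `r = −ln(1 − p)`, rates of
competing exits are summed, the total exit probability is
`1 − exp(−Σr)`, and it is apportioned among exits by rate share. This
keeps transition rows stochastic for any admissible inputs and is
standard in state-transition modelling. Background mortality applies in
every alive state, including recurrence, as a competing risk.

Life-table entries are annual; the monthly probability assumes a
constant hazard within the year, `p_m = 1 − (1 − p_a)^{1/12}`, with age
indexed as `start_age + floor(month / 12)`. The table must reach
probability 1 at age 85; any cohort fraction still alive at the final
boundary is moved to death from other causes (terminal forcing).

Accrual uses a half-cycle (trapezoidal) correction: cycle *t* accrues
at the mean of the state occupancies at boundaries *t* and *t + 1*.
Discounting is 5 %/year, `(1.05)^{−t/12}` at the cycle's starting
month, applied identically to costs and health outcomes; overall
survival is reported undiscounted.

## Calibration

Monthly recurrence probabilities derive from digitized Kaplan–Meier
disease-free / recurrence-free survival coordinates:

1. a shape-preserving cubic (PCHIP) interpolates log-survival exactly
   through the digitized points (a smoothing-spline variant is
   available for noisy digitizations); fitted monthly values are
   isotonically projected (running minimum) and clipped to [0, 1], and
   the fit must pass within 0.5 percentage points of every input point;
2. the discrete monthly hazard is `p(m) = (S(m) − S(m+1)) / S(m)`;
3. beyond the trial follow-up the last fitted monthly hazard is carried
   forward to the cure month (alternative: an exponential rate fitted
   to the final 24 months); after month 96 the probability is exactly 0.

Validation compares the model's disease-free survival at a trial
landmark with the curve it was calibrated to. The default convention
renormalizes disease-free occupancy to exclude background (non-cancer)
deaths — under the rate-combination rule this recovers the recurrence
survival curve exactly, so a model built from a curve reproduces that
curve's landmark to numerical precision — with a flag to compare raw
disease-free occupancy (which counts background deaths as events, the
trial DFS convention). A practical note on digitization density: a
decreasing-hazard (Weibull shape < 1) curve has a steep early hazard
that no smooth interpolant can recover from 6-monthly coordinates;
monthly probabilities at months 1–3 are only reliable when the curve is
digitized at (near-)monthly resolution, which is what step-by-step
tracing of a published curve yields.

## Economics

Costs are societal, in 2020 international dollars (ZAR 6.86 = I$1).

* **Adjuvant phase** (months 0 to 3 or 6): drug, personnel, antiemetics
  and bloodwork accrue monthly; the administration component (port-a-
  cath and infusion pumps for the infusional FOLFOX arms; I$2,416.33
  per course for FOLFOX 6MO) is spread over the treatment months, as
  are expected adverse-event costs (Σ probability × unit cost over six
  treatment-related adverse events). Visit counts follow the oral-vs-
  infusional pattern (FOLFOX 6MO 12, CAPOX 6MO 8, capecitabine 8,
  FU/LV 30 over the course; 3-month arms scaled by half), each visit
  costing a public-transport round trip (I$6.03) plus eight hours of
  lost wages (I$2.52/h) for the patient and one caregiver.
* **Disease-free follow-up**: surveillance cost per month plus indirect
  costs for surveillance visits (default one visit per three months).
* **Recurrence**: first-line chemotherapy for 6 months, second-line for
  6 months, then best supportive care, each with monthly cost, expected
  adverse-event costs, and visit-based indirect costs; hepatectomy is a
  one-time cost applied to 1/9 of recurrence entries (1/3 liver-only ×
  1/3 resected) at the entry boundary. No survival benefit is attached
  to hepatectomy — the inputs specify only its cost and fractions.

DALYs are YLL + YLD without age-weighting on the study's 0-to-1
disability scale (1 = death from colon cancer). YLD accrues weighted
alive person-time: the recurrence weight (default 0.45), transient
adverse-event disability spread over the treatment months or metastatic
lines, and a one-time post-hepatectomy term. YLL accrues at weight 1
while the cohort occupies the colon-cancer-death state, up to the model
horizon (age 85); death from other causes accrues nothing. This
"within-model" YLL reference reproduces the comparator logic without an
external life-expectancy table; a standard life-expectancy YLL could be
swapped in at the accrual layer.

Comparative analysis: strongly dominated strategies (costlier, no more
effective) are removed, then extendedly dominated ones (ICER above that
of a more effective strategy) iteratively; pairwise ICERs along the
remaining frontier strictly increase. The optimal strategy maximizes
NMB = WTP × DALYs averted − cost at WTP I$13,006.56/DALY averted; this
is provably the most effective frontier strategy whose ICER does not
exceed the WTP, and the equivalence is property-tested. Ties on equal
effectiveness keep the cheaper strategy; identical (cost, effect) pairs
are both kept and flagged equivalent.

## Sensitivity analysis

* **One-way DSA**: each parameter (addressed by dotted path) is set to
  its low and high bound with everything else at base; the full
  analysis re-runs and the tornado reports the headline ICER — the
  frontier strategy just above the NMB-optimal one versus the optimal
  (or the optimal's own ICER when it tops the frontier) — sorted by
  swing.
* **PSA**: parameters with attached distributions are redrawn
  simultaneously and independently each iteration — beta for
  probabilities and disability weights, gamma for costs (both
  parameterized by the base-case mean and a coefficient of variation,
  default 0.2), and mean-one log-normal multipliers on each strategy's
  recurrence hazard (σ = 0.1, spanning roughly ±20 %). Draws outside a
  parameter's admissible range are redrawn (cap 100). Strategies whose
  transition inputs carry no distribution reuse the base cohort trace
  and only re-accrue costs and DALYs, which keeps large PSAs cheap;
  zero-variance distributions reproduce the base case exactly.
* **CEAC**: stored (cost, effect) draws are re-scored by NMB argmax on
  a WTP grid (default 25 points, I$6,503.29–39,019.72) without
  re-simulation; probabilities at each grid point sum to 1.

Independent draws are a stated limitation: real cost and effectiveness
parameters are correlated, and ignoring that typically overstates
decision uncertainty.

## Synthetic inputs and the microsimulation oracle

The original input tables (digitized trial curves, pooled
post-recurrence survival, WHO life table, fee-schedule costs) are not
redistributable here, so the generator emits complete stand-ins with
the same structure and realistic magnitudes:

* per-strategy recurrence hazards: Weibull, shape 0.8 (decreasing
  hazard), no-chemotherapy scale 62 months (≈ 55 % recurrence by five
  years, typical of untreated stage III disease), with hazard ratios
  0.48–0.70 ordered so oxaliplatin doublets beat fluoropyrimidine
  monotherapy, FOLFOX 6MO slightly beats FOLFOX 3MO, and CAPOX 3MO ≈
  CAPOX 6MO; risk multipliers 0.6 (low risk) and 1.5 (high risk);
* a Gompertz-like life table, base annual probability 0.02 at 60
  growing 9 %/year (heavy background mortality appropriate to the
  setting), 1.0 at 85;
* post-recurrence monthly death probabilities declining with months
  survived (base 0.060/0.050/0.040 for early/mid/late recurrence,
  decay 0.985/month, floor 0.015 — median post-recurrence survival
  on the order of 1–2 years, worse for early recurrence);
* cost schedules, six-event adverse-event profiles and disability
  weights of plausible magnitude.

These values are deliberately **not** fitted to the published headline
numbers — doing so would make any reproduction circular. Passing tests
therefore demonstrate that the machinery (calibration, engine, accrual,
frontier, PSA) is correct and internally consistent, not that the
published point estimates are recovered; recovering them requires
transcribing the original input tables into a parameter file, which the
config layer accepts.

The microsimulation oracle simulates individual monthly trajectories
from the same transition probabilities and accrual rules as the cohort
engine (by construction — the two must agree in expectation) but
replaces expectation propagation with Monte Carlo sampling, so it
detects any defect in the cohort algebra: tunnel bookkeeping, entry
flux, half-cycle accrual, discount timing, terminal forcing. The test
suite checks 20 random parameter sets at n = 200,000 (cost, DALYs and
OS within 3 SE; occupancies within a family-wise 3σ bound across the
360 state-month comparisons), and additionally checks the engine
against a naive per-cycle matrix product built from the scalar
transition rows at machine precision, which is sharper than any
Monte Carlo bound.

## Numerical choices and problem sizes

Double precision throughout; trace rows must sum to 1 within 1e-9 (an
internal-consistency error otherwise). The engine is vectorized over
the tunnel grid; one strategy evaluation (trace + accrual) takes a few
milliseconds, so the default test suite runs in well under two minutes
and the acceptance script in about one and a half. Reported problem
sizes: PSA n = 2,000 in the acceptance script (n = 10,000 in the
calibrated-coin test; the method scales linearly to the 100,000 used in
large published analyses), microsimulation n = 100,000–200,000,
1,000 random parameter sets for conservation checks.

## Known limitations

* No patient-level heterogeneity beyond the risk-stratified scenario;
  no stage I/II/IV index disease, rectal cancer, or biologic agents.
* Hepatectomy carries cost and transient disability but no distinct
  survival trajectory (no such input exists in the source material).
* Metastatic line durations (6 + 6 months) and surveillance/metastatic
  visit schedules are configuration defaults, not published values.
* PSA draws are independent across parameters.
* The YLL reference is the within-model horizon (age 85), not a
  standard life table, so absolute DALY totals are not comparable to
  global-burden estimates; DALYs *averted* between arms are.
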
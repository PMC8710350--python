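# coloncea

A decision-analytic Markov cohort model for the cost-effectiveness of
adjuvant chemotherapy in stage III colon cancer, set in South African
public hospitals and evaluated from the societal perspective.

The package is for health-economics researchers and analysts who want a
fully scriptable, testable implementation of this class of model:
six adjuvant regimens — FOLFOX for 3 and 6 months, CAPOX for 3 and
6 months, capecitabine for 6 months, and fluorouracil/leucovorin (Mayo)
for 6 months — are compared against surgery alone over a lifetime
horizon, with costs in 2020 international dollars (ZAR 6.86 = I$1) and
health effects in disability-adjusted life-years (DALYs) averted.

## The model

A cohort of 60-year-old patients enters disease-free after curative
resection and is propagated in 1-month cycles for 300 months (to age
85), with a half-cycle correction. From the disease-free state patients
may recur (distant metastases) or die of other causes; recurrence is
stratified by its timing (0–2, 2–3, > 3 years after surgery) and
expanded into monthly tunnel states so that colon-cancer mortality can
depend on both the timing of recurrence and the time already survived
in recurrence. Patients disease-free for more than 96 months are cured.
One third of recurrences are liver-only and one third of those undergo
curative-intent hepatectomy (a one-time cost). Metastatic treatment is
at most two chemotherapy lines, then best supportive care; no biologics.

Monthly recurrence probabilities come from digitized Kaplan–Meier
disease-free/recurrence-free survival coordinates via a monotone spline
on log-survival, `p(m) = (S(m) − S(m+1)) / S(m)`, extrapolated from the
trial end to the cure month. Background mortality uses an age-indexed
life table reaching probability 1 at age 85. Competing monthly risks
are combined on the rate scale (`r = −ln(1−p)`, rates summed, total
exit probability apportioned by rate share).

Outcomes per strategy:

* **cost** — discounted (5 %/yr) lifetime societal cost: adjuvant drug/
  personnel/administration/antiemetics/bloodwork, adverse events,
  surveillance, metastatic lines, hepatectomy, plus transport and a day
  of lost wages per visit for the patient and one caregiver;
* **DALYs averted** vs no chemotherapy — YLL + YLD, discounted, no
  age-weighting, disability scale 0 (healthy) to 1 (death from colon
  cancer);
* **OS** — undiscounted life-years;
* **ICER** along the efficiency frontier (strong and extended dominance
  removed) and **NMB = WTP × effect − cost** at the willingness-to-pay
  threshold I$13,006.56/DALY averted (2020 ZA GDP per capita).

One-way deterministic sensitivity analysis (tornado), probabilistic
sensitivity analysis (beta/gamma/log-normal parameter distributions)
and cost-effectiveness acceptability curves over WTP from I$6,503.29 to
I$39,019.72 are built in, as is a risk-stratified scenario restricted to
the four oxaliplatin-based arms.

The original study's input tables are not machine-readable, so the
package ships a synthetic-data generator that emits complete,
realistic, *untuned* inputs of the same structure, plus an
individual-level microsimulation oracle used to verify the cohort
engine (see `docs/methods.md`).

## Worked example

```python
from coloncea import MarkovCEA

results = MarkovCEA.from_synthetic(seed=0).fit()
print(results.summary())
```

```
Markov cohort cost-effectiveness results
======================================================================================
comparator: NO_CHEMO    WTP: I$13,006.56/DALY averted    discount: 5%/yr
horizon: 300 months from age 60    parameters: 475453d2633c169c
--------------------------------------------------------------------------------------
strategy               cost I$  DALYs averted   OS yrs        ICER      NMB I$  dominance
--------------------------------------------------------------------------------------
NO_CHEMO              9,206.66          0.000     7.19          --      -9,207  on_frontier
FULV_6MO             12,167.35          1.461     8.77          --       6,830  strongly_dominated
CAPECITABINE_6MO     11,321.54          1.759     9.09          --      11,552  strongly_dominated
FOLFOX_3MO           11,715.38          2.537     9.94          --      21,281  strongly_dominated
CAPOX_6MO            11,712.19          2.672    10.09          --      23,048  strongly_dominated
CAPOX_3MO            10,193.50          2.749    10.17         359      25,559  on_frontier
FOLFOX_6MO           14,258.05          2.889    10.33      28,947      23,321  on_frontier
--------------------------------------------------------------------------------------
optimal at WTP: CAPOX_3MO
```

Reading the table: every adjuvant regimen averts DALYs and carries a
positive net monetary benefit relative to surgery alone; the dominated
arms are removed from the frontier; CAPOX 3MO is optimal because the
next frontier step (FOLFOX 6MO, ICER I$28,947 per DALY averted under
these synthetic inputs) costs more per DALY than the willingness-to-pay
threshold. Sensitivity analyses hang off the results object:

```python
psa = results.run_psa(n=1000, seed=1)
print(psa.probability_optimal)          # P(strategy is optimal) at the WTP
curves = results.ceac(psa)              # acceptability over the WTP sweep
results.plot_ce_plane()                 # cost-effect plane with frontier
```

The same pipeline is scriptable from the shell:

```sh
coloncea run --config examples/base_case.yaml --out out/
coloncea psa --config examples/base_case.yaml --n 1000 --seed 7 --out out/
coloncea scenario --config examples/base_case.yaml --scenario high_risk
coloncea synth --seed 0 --out inputs/      # emit synthetic input bundle
coloncea calibrate --km inputs/km_CAPOX_3MO.csv --trial-end 60
```

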
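# dfucea

A Markov cohort cost-utility model for adjuvant **recombinant human
epidermal growth factor (rhEGF)** versus conventional wound care alone in
patients with **Wagner grade 3–4 diabetic foot ulcers**, from a health-system
perspective (Colombia; costs in USD, threshold 3× GDP per capita).

It is written for health economists and HTA analysts who want a scriptable,
testable version of this class of spreadsheet decision model: a weekly-cycle
state-transition cohort model with per-patient cost and QALY accrual, ICER
computation, and multivariate Monte Carlo sensitivity analysis.

## The model

Patients start with an open ulcer and move weekly between five states

```
open_ulcer ──p_close──▶ healed
    │ p_amp──▶ post_amputation          (amputation event; a fraction
    │              │                     p_death_amp dies of the procedure)
    └─p_dis──▶ dead_disease ◀──p_dis────┘
```

with mutually exclusive competing transitions per cycle: complete wound
closure (`p_close`: 0.0398/week rhEGF, 0.0129 conventional), amputation
(`p_amp`: 0.0164 / 0.0308), and disease death (`p_dis` = 0.0003/week, applied
to every alive state). Death from the amputation procedure (0.0029) is
applied once, at the event. Over a 5-year horizon (260 cycles) the model
accrues:

* **amputations per patient** — the sum of weekly amputation flows;
* **QALYs** — state occupancy × annual utility weight / 52, discounted at
  5%/year with per-week compound factors `(1+r)^(-w/52)`;
* **costs (USD)** — weekly wound care (343.04/week while the ulcer is open,
  both arms), rhEGF vials (3 × 762.87/week for the 8-week application
  window), amputation surgery + prosthesis at the amputation event, and
  rehabilitation at closure;

and compares the arms by the incremental cost-effectiveness ratio
`ICER = ΔC/ΔE` against a willingness-to-pay threshold of 3 × 17,696 =
53,088 USD/QALY. The probabilistic sensitivity analysis redraws every
probability and unit cost uniformly within ±20% of its base value and
classifies each iteration on the cost-effectiveness plane (dominant / below
threshold / above threshold / dominated).

Utility weights are not published for this model; the shipped defaults
(`u_open = 0.5319`, `u_healed = 0.95`, `u_post_amputation = 0.6047`) are
**calibrated** so the base case reproduces the published per-arm QALYs
(3.98 / 3.32) — see `docs/methods.md`.

## Worked example

```bash
$ dfucea base-case --out out/
Delta cost (disc.) 12,266.03 USD, Delta QALY (disc.) 0.58, ICER 21,030.70 USD/QALY -> cost_effective_below_threshold
$ head -3 out/outcomes.csv
strategy,amputations,amputations_discounted,qalys,qalys_discounted,cost_usd,cost_usd_discounted
rhEGF,0.29,0.29,3.98,3.53,22345.29,22186.91
conventional,0.7,0.69,3.32,2.94,10125.2,9920.88
```

Reading: conventional therapy leads to 0.70 expected amputations per patient
(the competing-risk limit 0.0308/0.0440), rhEGF to 0.29 — about 0.4
amputations averted per patient. rhEGF gains 0.58 discounted QALYs at an
extra discounted cost of 12,266 USD, an ICER of ~21,031 USD/QALY, well below
the 53,088 USD/QALY threshold: rhEGF is cost-effective. The Monte Carlo
analysis checks robustness:

```bash
$ dfucea psa --n 200 --seed 7 --out out/
PSA (200 iterations, seed 7): dominant: 0.0%, cost_effective_below_threshold: 100.0%, above_threshold: 0.0%, dominated: 0.0%
```

The same API is available in Python:

```python
import dfucea
params = dfucea.generate_base_case()
result = dfucea.compare_strategies(params)
print(result["incremental"]["icer"])      # 21030.695...
```

Other commands: `dfucea tornado` (one-way sensitivity, ICER at each
parameter's ±20% bounds), `dfucea trace` (weekly cohort trace as CSV),
`dfucea calibrate-utilities` (fit utilities to QALY targets). All commands
accept `--param-file` with a YAML parameter file; the shipped base case is
`src/dfucea/data/base_case.yaml`.

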
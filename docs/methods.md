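# Methods

## Model structure and assumptions

The model is a discrete-time Markov cohort model with weekly cycles over a
5-year horizon (260 cycles). States: `open_ulcer` (initial, occupancy 1.0 at
week 0), `healed`, `post_amputation`, and two absorbing death states tagged
by cause (`dead_disease`, `dead_amputation`). Competing transitions out of
the open state are applied as a single multinomial row per cycle — the
probabilities are used as given and sum to less than 1, with the remainder
staying open; they are not chained as sequential conditional draws.

Key structural choices, each exposed as a parameter or flag:

* **Peri-operative mortality** (0.0029) multiplies the amputation
  probability at the event (`p_amp × p_death_amp` to `dead_amputation`,
  `p_amp × (1−p_death_amp)` to `post_amputation`); it is not a weekly hazard
  on the post-amputation state.
* **Disease death** (0.0003/week) applies to all alive states, including
  `healed`; `SharedParams.healed_disease_death=False` disables it for the
  healed state. At 0.0003/week the two readings differ by less than the
  printed precision of any output.
* **Closure onset**: `closure_onset_week` suppresses closure transitions
  before a given week (clinical reports place first closures around week
  11 rhEGF / 14 conventional). The default is 1 (no suppression): with
  suppression the conventional arm's expected amputations rise to ~0.80,
  contradicting the published 0.70, which equals the constant-hazard
  competing-risk limit 0.0308/(0.0129+0.0308+0.0003) ≈ 0.700. The onset
  delay is therefore an exploratory switch, not part of the base case.
* **No half-cycle correction** by default (the accrual matches start-of-cycle
  billing for recurring costs and end-of-cycle occupancy for QALYs, as in
  spreadsheet implementations); `half_cycle=True` averages start/end
  occupancy in the accrual functions.

## Parameters

Weekly probabilities (with ±20% uniform sensitivity ranges): closure 0.0398
(rhEGF) / 0.0129 (conventional); amputation 0.0164 / 0.0308; disease death
0.0003; peri-operative amputation death 0.0029. Non-closure complements are
always derived (1 − closure), never stored or sampled, so multinomial rows
stay coherent; their printed capped ranges (e.g. 0.7682–1.0000) are
reproducible via `build_range(0.9602, cap_at_one=True)`.

Unit costs (USD): rhEGF vial incl. application 762.87 (3 vials/week for an
8-week window → 2,288.61/week); weekly conventional wound-care bundle
343.04 (the six printed components — room 40.36, procedure 121.33, saline
13.54, gauze 135.39, bandages 26.91, counselling 5.51 — round-sum one cent
below their printed 343.05 total); prosthesis 1,965.22 under-knee /
3,049.48 over-knee; amputation surgery 1,488.53; rehabilitation after
closure 408.80.

Economic settings: 5%/year discount rate applied as per-week compound
factors `(1+r)^(-w/52)`; threshold 3 × GDP per capita (17,696 USD) =
53,088 USD/QALY; exchange rate 2,951.35 COP/USD.

## Billing conventions

The weekly wound-care bundle is billed to both arms while the ulcer is open
(rhEGF is an adjuvant on top of conventional care), uncapped in time. Within
an arm it is categorised as active therapy while the week index is inside
the arm's treatment window (8 weeks rhEGF; the whole horizon for the
conventional arm) and as continued wound care of non-closed patients
afterwards. Drug cost is billed while open and inside the window. Surgery is
billed per amputation event including procedure deaths (the surgery
happened); the prosthesis is billed per surviving amputee, mixing an
(unpublished) 50/50 over/under-knee amputation-level split with the
level-specific fitting rates (100% over-knee, 15% under-knee) — the split is
a parameter (`frac_amputations_over_knee`). Rehabilitation is billed once
per closure.

Under these conventions the per-arm totals land near, not on, the published
cost table (22,345 vs 19,024 USD rhEGF; 10,125 vs 11,346 conventional): the
published drug totals imply ~7.55 billed rhEGF weeks (consistent with a
~10-week closure suppression) while its amputation totals imply none, so no
single convention reproduces every published cell. The package anchors on
the transition structure and documents cost totals as approximate.

## Discounting of amputation counts

QALYs and costs are discounted at the week they accrue. For the *amputation
count* the published base-case table is only reproducible by applying the
end-of-horizon factor `1.05^-5 ≈ 0.7835` to the undiscounted totals
(0.70→0.55, 0.31→0.24, incremental 0.32); weighting each amputation by the
factor at its event week — the statistically standard choice — gives
0.685/0.286 because amputations concentrate in the first year.
`expected_amputations_discounted` therefore takes
`method="event_week"` (default) or `"end_of_horizon"` (used when mirroring
the published table).

## Utility calibration

No utility weights are published. QALYs are linear in the three alive-state
weights, so fixing `u_healed` leaves a 2×2 linear system in
(`u_open`, `u_post_amputation`) built from each arm's state person-years,
fitted to the published per-arm undiscounted QALYs (3.98 / 3.32). With
`u_healed = 1.0` the solution is infeasible (`u_open = −0.38`); the feasible
`u_healed` interval is ≈ [0.921, 0.971]. The shipped defaults pin
`u_healed = 0.95` (mid-interval, and close to published healed-ulcer
utilities elsewhere in the diabetic-foot literature), giving
`u_open = 0.5319`, `u_post_amputation = 0.6047`. These are calibrated, not
elicited, values; `calibrate_utilities` reports the non-uniqueness (a
one-parameter family over `u_healed`) and the feasible interval in its
diagnostics. The calibrated set reproduces the published discounted QALYs
(3.53/2.94 vs 3.51/2.93) with no further fitting.

## Sensitivity analysis

The PSA draws every ranged parameter independently and uniformly on its
±20% range (matching the printed min/max columns), recomputes derived
quantities (weekly drug cost from the vial price, complements), validates
the draw (invalid rows are resampled and counted, never dropped), reruns
the whole pipeline, and classifies the discounted (ΔC, ΔE) pair on the CE
plane. Utilities are excluded from sampling because their base values are
themselves calibrated. The published iteration split (78.1% below / 16.4%
above / 4.2% dominant) is not reproducible under this joint distribution:
with derived complements the sampled ICER stays within ~10–39k USD/QALY and
Δcost stays positive, so at n=1,000 all iterations are below the threshold.
The published spread is consistent with sampling the complement rows
(0.7682–1.0000) as independent variables, which this package deliberately
does not do; no correlation structure is published, and independence across
sampled parameters is assumed. The CEAC is computed from net monetary
benefit (`NMB = λΔE − ΔC > 0`); the one-way tornado analysis evaluates the
ICER at each range's bounds.

## Scenario generator and oracles

`generate_base_case` builds the canonical parameter set in code; a YAML
copy ships with the package and must round-trip identically. Toy scenarios
carry closed forms (eventual amputation fraction `p_amp/(p_close+p_amp+p_dis)`,
expected open weeks `1/(p_close+p_amp+p_dis)`), recomputed at construction,
and are checked against 10,000-cycle engine runs to 1e-6. The
microsimulation oracle simulates individual patients with inverse-CDF draws
against the exact multinomial rows the cohort engine uses (vectorised over
patients; one generator stream per run, seeded); cohort occupancies must
agree with its means within 3 Monte Carlo standard errors. The generator
emulates parameter files and cohorts of this decision model only — it does
not simulate wound-size trajectories, ulcer recurrence, readmissions, or
patient heterogeneity, so passing tests validate the model's internal
consistency and its published-table arithmetic, not clinical prediction.

## Numerical choices and problem sizes

Probability conversions use `expm1`/`log1p` to stay accurate near 0 and 1;
`rescale_probability` rejects p = 1 (infinite rate). Transition rows are
validated to sum to 1 within 1e-12 and traces to conserve mass within
1e-10. Ties at ΔE = 0 classify by cost sign alone; ΔC = ΔE = 0 counts as
cost-effective (the strategies are identical). Default problem sizes:
260-cycle cohorts (milliseconds), 1,000 PSA iterations (~2 s), 200,000
microsimulation patients for the strictest oracle check and 20,000 in
routine tests.

## Known limitations

Two strategies only (no efficiency frontier or extended dominance); no
value-of-information analysis; no indirect or out-of-pocket costs; no
post-amputation excess mortality beyond the one-off procedural risk; cost
totals match the published tables approximately for the reasons above.
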
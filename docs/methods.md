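# Methods

## The model

`cycleval` appraises a cycling-infrastructure investment with a
comparative risk assessment: two population steady states — before and
after a change in the distribution of adults over five cycling-frequency
levels — are compared directly, without simulating individuals or
recurrent events. Four domains are monetised:

1. **Physical activity.** Each frequency level implies an annual cycling
   volume `v = days/year × trips/day × km/trip`. All-cause mortality is
   scaled by a relative risk linear in volume,
   `RR(v) = 1 − (1 − RR_ref) · min(v / v_ref, c)`,
   with `RR_ref = 0.90` at `v_ref = 1200 km/year` (roughly 100 minutes of
   cycling a week at 14 km/h) and cap `c = 2`: beyond twice the reference
   volume no further protection accrues. The deaths delta is the
   population-expected deaths under the post distribution minus baseline.
2. **Air pollution.** The incremental cycling kilometres imply hours of
   exposure (at 14 km/h). During the in-traffic fraction of those hours
   the inhaled dose exceeds rest by `(ventilation − 1) × PM2.5`; the
   resulting annual-average equivalent exposure increase raises mortality
   proportionally (0.8% per µg/m³ by default). Always a disbenefit.
3. **Crash risk.** Incremental km × a fatality rate per 100 million km
   cycled (default 1.8). Always a disbenefit.
4. **Carbon.** Incremental cycling km displace km on prior modes in the
   modal-shift proportions (default 50% public transport / 30% car / 20%
   walking) with per-mode emission factors (80 / 171 / 0 g CO2 per km),
   valued at a damage cost per tonne (default $100).

Mortality domains are valued at the value of a statistical life (VSL);
averted deaths are positive value. Each annual steady-state value `a` is
converted to present value with a linear demand ramp and end-of-year
discounting over the horizon `H`:

    PV(a) = Σ_{t=1..H}  min(t / takeup, 1) · a · (1 + r)^(−t)

The benefit-cost ratio (BCR) divides the summed present values by the
construction cost. Both are held in international dollars; a purchasing
power parity (PPP) coefficient (0.667865) converts to pounds where
reported.

## Break-even solving

For each source level 2–5, the solver finds the share of the total
population that must move from that level to level 1 ("daily or almost
daily") so that BCR = 1. The benefit is monotone — in fact linear — in the
shifted share, so bisection over `[0, baseline source share]` converges
unconditionally; the default tolerance is |BCR − 1| ≤ 1e−6. The first
upper probe is the share lifting level 1 to 5% of the population (the
customary "400% increase" planning target), widened to the full source
share if insufficient; results are bracket-independent. Counts of new
regular cyclists are kept continuous during solving and rounded half-up
only at reporting time. The four-scenario summary reports the rounded mean
count, cyclists per km of cycleway (mean count / length), and the annual
value per additional regular cyclist (cost / (mean count × horizon) —
equal to the annual benefit per cyclist, since benefits equal cost at
break-even). The mean requirement is reported both as the mean of the four
solved shares and as mean count / population; the two differ slightly
because counts are rounded per scenario.

## Sensitivity analysis

One parameter is replaced at a time; each row reports (a) the BCR the
base-case break-even shift would achieve under the varied parameter and
(b) the re-solved break-even from level 2, as a share, an absolute number
of regular cyclists (pre-existing ones included), and the difference from
the base-case absolute count. The standard grid has 20 rows: two age
cohorts (implemented as swapping the cohort's annual mortality rate only),
VSL ±20%, discount rate ±1.5 percentage points (absolute), horizons of 5
and 15 years, trip length and trips/day ±20% — separately for the
*baseline* behaviour (applied to both states: everyone's trips change) and
the *post* behaviour (applied to the post state only, which moves the BCR
much further because it changes the incremental volume directly) — take-up
times of 2/3/5 years, and 100% in-traffic cycling.

When a post-only behaviour boost makes the zero-shift state already
cost-saving, the equilibrium lies at a *negative* shift (fewer regular
cyclists than baseline); `run_variation` bisects that branch, bounded by
emptying level 1, so such rows stay informative instead of erroring. A
variation whose break-even is genuinely unreachable (source level
exhausted) is flagged infeasible with the BCR still reported.

## Parameters and defaults

The Coventry fixture pins the published case-study inputs: population
173,169 adults (18+ within two miles of the route) distributed
(1, 9, 15, 25, 50)% over the five levels; cost $12,800,491 international
(6 km of separated cycleway); VSL $4,260,000; 5% discount; 10-year
horizon; 1-year take-up; 2.0 trips of 4.1 km on a cycling day. Two
published inconsistencies are handled by decision: the dollar cost is
stored as printed rather than recomputed from £8,594,000 via the PPP
coefficient (the recomputation differs by ~0.5%), and the population count
is 173,169 throughout (one printed passage says 173,649).

The level→days mapping (312 / 104 / 24 / 6 / 0 days/year) uses midpoints
of the category ranges and is configurable via `AppraisalConfig.levels`;
all the headline summary arithmetic is independent of it. Background risk
parameters (mortality rate 0.0023 for ages 20–64, with 0.00085 and 0.0046
for the 20–44 and 45–64 cohorts; the dose-response, exposure, crash and
emission defaults above) follow the public health-economic-assessment
literature for UK urban settings. They are *defaults, not a reproduction*:
the case study's own appraisal used a proprietary tool whose internal
background datasets are not public, so this package's modelled break-even
(1,451 new regular cyclists from level 2 under the defaults) sits at the
same order of magnitude as the published 2,151 but is not expected to
match it. The headline per-cyclist and per-km statistics, by contrast, are
pure arithmetic on the published scenario tables and are reproduced
exactly.

## Numerical choices

- Discounting is end-of-year (`timing="mid"` available on
  `discounted_stream`); the published values imply a discount-and-ramp
  factor matching no simple convention, so the simplest one is the default
  and documented.
- The uptake ramp is linear, `min(t/takeup, 1)` — the simplest monotone
  choice; it reproduces the published direction of the take-up rows.
- Share mass sums are checked to 1e−9; probability-mass updates touch only
  the two affected components, so conservation is exact to rounding.
- Rounding of person counts is half-up (`floor(x + 0.5)`), applied only at
  reporting boundaries.
- `validate_config` reports *all* violations rather than raising on the
  first; generated and loaded configs pass through it before any engine
  call.

## What the synthetic generator does and does not emulate

`sample_configs` draws structurally valid configurations: a symmetric
Dirichlet over the five shares (each level's share has mean 1/5),
log-uniform VSL in [$1M, $10M], uniform discount in [0, 0.1], horizons
5–20 years, take-up 1–5 years capped at the horizon, plus uniform ranges
on population, behaviour, cost and risk parameters. This exercises the
engine's algebra (linearity, monotonicity, sign structure) and the
solver's convergence across a wide parameter box. It does not emulate
realistic joint distributions of these parameters, travel-diary
variability, seasonal cycling patterns, or correlation between baseline
cycling levels and urban form — so passing property tests demonstrate
model correctness, not calibration to any real city.

## Known limitations

Mortality only: no morbidity, quality-adjusted life years, travel-time or
congestion effects — the appraisal is deliberately conservative and
complements, not replaces, full transport appraisal. Single-source shifts
only: real uptake draws from a mix of the four lower levels. No
probabilistic sensitivity analysis: uncertainty is explored one parameter
at a time. Exposure domains apply to the incremental kilometres only, not
to route-switching by existing cyclists.
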
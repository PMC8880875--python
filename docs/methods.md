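# Methods

## Model structure and assumptions

The model is a deterministic Markov cohort (expectation) model: occupancy
is a real-valued mass over five mutually exclusive PTSD severity states
plus death, advanced in annual cycles.  Its central simplification is that
*severity is static among the living*: the treated arm jumps to the trial's
follow-up severity mix at time zero and each arm's members then stay in
their category until death.  The treatment effect is therefore entirely the
difference between the intake and follow-up mixes — no remission, relapse
or spontaneous drift occurs in the base case (the progression scenario
relaxes this one-sidedly for the treated arm).  This matches the long mean
illness duration of the modelled population (chronic PTSD of about 14
years), for which spontaneous remission is rare.

Each arm is simulated independently over the same cohort:

1. **Age strata.** The cohort age distribution (normal, mean 41, SD 11.9)
   is discretized into one-year strata on [18, 90], weights renormalized.
   Every stratum ages along its own life-table path.  Because the death
   probability q(a) is convex in age, the stratified cohort has ~65% higher
   year-1 mortality than a single stratum at the mean age; this convexity
   correction is deliberate (see *Fidelity*, below).
2. **Mortality.** In cycle *t* a stratum at age *a* in state *s* dies with
   probability min(1, RR_s · q(a)).  Relative risks multiply the background
   probability directly; the product is capped at 1.  Ages beyond the life
   table clamp to its last row (a warning is logged once).
3. **Accrual.** Deaths occur at cycle end; costs and QALYs accrue to the
   survivors of the cycle and are discounted with the end-of-cycle factor
   (1+r)^-t.  There is no half-cycle correction.  The alternative
   "entrant" convention (credit everyone alive at cycle start) is available
   via `run_cohort(..., accrual="entrant")`; it raises both arms' costs and
   QALYs by roughly half a cycle's worth and was not adopted because the
   survivor convention reproduces the published one-year arm costs almost
   exactly (control: modelled $20.59M vs printed $20.63M).
4. **Cost offset ramp.** The treated arm's achievable per-capita saving is
   the baseline difference between the intake-mix and follow-up-mix
   per-capita annual costs (Δ ≈ $10,100/person-year).  The ramp releases
   0/25/50/75/100% of Δ in years 1–5.  The intake→follow-up mapping of
   *individuals* is unobserved, so the offset is applied at arm level: each
   cycle the treated arm is billed its actual surviving state mix plus
   (1 − ramp(t))·Δ per living member.  Billing the actual mix (rather than
   the fixed follow-up per-capita cost) keeps the two arms' accounting
   symmetric; because survivors drift toward the lower-mortality mild end,
   it credits the treated arm slightly larger savings at long horizons
   (30-year net cost −$116.6M vs −$112.9M under the fixed-mix reading).
5. **Intervention cost.** $11,537 × cohort size, charged undiscounted at
   time zero (treatment precedes the first model year).
6. **Mortality during the ramp** uses the achieved (follow-up) state from
   cycle 1 onward: the ramp phases in cost savings only, not survival.

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| cohort size | 1,000 | persons | scale only; per-patient results divide through |
| horizon | 30 (also 1, 10) | years | analytic time horizon |
| discount rate | 0.03 (SD 0.0034) | /year | applied to costs and QALYs, not deaths |
| intake mix | 0/0/0/714/286 | persons | severity at trial entry |
| follow-up mix | 333/262/262/119/24 | persons | severity ~8 weeks after the third session |
| intervention cost | 9,828 + 909 + 800 = 11,537 (±30%) | USD/patient | one-time, year 0 |
| annual medical cost | 5,032 / 10,118 / 15,177 / 20,236 / 24,283 | USD/person-year | gamma-distributed (SDs 712…3,434) |
| mortality RR | 1.00 / 1.74 / 2.05 / 2.51 / 2.76 | — | lognormal (SDs 0.70…1.25); asymptomatic fixed |
| utilities | 0.90 / 0.83 / 0.74 / 0.61 / 0.37 (±10%) | — | beta-distributed QALY weights |
| mean age | 41 (SD 11.9) | years | shifts the whole age-stratum grid |
| cost-offset ramp | 0, .25, .50, .75, 1.0 | fraction | savings released by year since treatment |
| progression risk | 0.10 (uniform 0.05–0.15), after year 5 | /year | scenario analyses only |

## Synthetic life table

The bundled background-mortality table is a Gompertz hazard
q(a) = 1 − exp(−A·e^{b(a−41)}) anchored at q(41) = 0.0020 with slope
b = 0.085/year (hazard doubling every ≈ 8.2 years).  It emulates the level
and log-linear rise of U.S. adult all-cause mortality without bundling any
external data; a real single-year table can be substituted as a CSV with
identical schema.  What it does *not* emulate: the late-teen/young-adult
accident hump (young q are understated), sex stratification, and the
old-age deceleration of the Gompertz law; contemporary U.S. tables also
rise somewhat more slowly (doubling ≈ 9 years), so the synthetic table
runs 10–20% high around ages 60–75.  Passing tests therefore demonstrate
the model mechanics and the published-value checks under *this* mortality
schedule, not actuarial fidelity to any specific national table; the slope
and anchor are ordinary parameters (`GompertzParams`) for users who want a
different schedule.

## Uncertainty conventions

- Families: gamma for costs (shape m²/s², scale s²/m), lognormal for
  relative risks (σ² = ln(1+s²/m²), μ = ln m − σ²/2), beta for utilities
  and the discount rate (moment-matched on [0,1]), beta on the scaled
  interval [0.7c, 1.3c] for the intervention-cost total, truncated normal
  for the mean age.  All draws are mutually independent.
- Where only a ± range is stated (intervention cost ±30%, utilities ±10%)
  the range is read as a 90% interval: SD = half-range / 1.645.
  Conversely, tornado bounds for SD-specified parameters default to
  central ± 1.645·SD.
- A sampled mean age rigidly shifts the whole age-stratum grid; the
  within-cohort age SD stays fixed.
- Sampled parameter sets are validated for domain constraints (positivity,
  [0,1] ranges) but *not* for cross-state ordering: the published per-state
  distributions overlap, and rejecting unordered draws would truncate the
  marginals.  Infeasible moment matching (e.g. a beta SD too large for its
  support) raises an error naming the parameter.
- PSA percentiles are the empirical 5th/95th (a 90% uncertainty interval);
  10,000 iterations take well under a minute.

## Numerical choices

- Break-even time interpolates the cumulative discounted net-cost path
  linearly within the bracketing cycle (the model is annual but a
  fractional year is the natural summary).  Net cost already non-positive
  at time 0 returns 0; no crossing returns infinity.
- The medical-cost scale threshold solves net cost = 0 by Brent's method on
  k ∈ [0, 1] (tolerance 1e-4), scaling only the per-state increment above
  the asymptomatic cost — the spending attributable to PTSD; scaling all
  costs is available via `mode="all"`.  With a zero intervention cost the
  threshold does not collapse exactly to 0: longer-lived treated patients
  still incur the asymptomatic cost floor, so k* ≈ 0.04.
- Life-table lookups interpolate linearly between tabulated ages and clamp
  at the ends.  Conservation of cohort mass (living + cumulative dead =
  cohort size) is asserted inside the engine at 1e-9 relative tolerance.
- ICERs are reported as ratios only for genuine trade-offs; dominance
  (cheaper and more effective, or the reverse) returns a flag, and a zero
  QALY difference with nonzero cost returns an undefined marker rather
  than raising.

## Fidelity to the published figures

The package reproduces the published cost-effectiveness quantities that are
driven by the severity mixes, prices and discounting essentially exactly:
30-year QALYs gained 4,865 (printed 4,856), 10-year QALYs 2,155 (2,163),
10-year savings $45.1M (46.6), break-even 3.78 years (3.8) with 888 QALYs
by then (887), one-year ICER $47,469 (47,554), no-savings ICERs $2,371 and
$5,353 (2,376 and 5,333), progression-scenario PSA means −$66.6M/3,131
QALYs (−$69.8M/3,018), and the three- vs two-session 1-year ICER $65,863
(66,704).

The mortality-*level* quantities do not reconcile, under any examined
convention, with the printed death totals: this model yields 121.7 deaths
averted at 30 years (printed 61.4) and 30-year net savings of $116.6M
(printed $132.9M).  The printed one-year arm deaths (control 6.9, treated
4.0) are themselves inconsistent with any model in this family: with a
shared age-mortality mix, year-one deaths are exactly proportional to each
arm's RR mix, forcing a ratio of 2.581/1.691 = 1.53, while the printed
ratio is 6.9/4.0 = 1.73 (the printed treated-arm value matches an RR mix
in which mild carries no excess mortality).  Varying the Gompertz slope,
the age truncation, or the accrual convention can match some of these
figures only at the expense of others, so the defaults above are kept and
the differences reported as-is rather than calibrated away.  Quantities
that depend on mortality only weakly (all the QALY-gain and ICER results)
are unaffected.

## Known limitations

- Payer perspective only: no productivity, unemployment or caregiver costs.
- No individual-level microsimulation; no within-life severity dynamics
  beyond the one-way progression scenario.
- The two-session regimen comparison consumes published result summaries;
  its efficacy distribution is not re-simulated.
- Utilities, costs and relative risks are treated as age-invariant.
- The synthetic life table's limitations are described above; analyses of
  populations much older or younger than the trial cohort should supply a
  real table.
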
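# mdma-cea

A Markov cohort cost-effectiveness model of MDMA-assisted therapy (MDMA-AT)
for adults with chronic severe or extreme posttraumatic stress disorder,
evaluated from the U.S. health-care payer's perspective.

Roughly half of PTSD patients do not respond meaningfully to standard
pharmacological or psychotherapeutic care, and severe PTSD carries both a
heavy personal toll and large recurring medical costs.  In a phase 3 trial,
MDMA-AT (three preparatory sessions, three drug sessions, nine integration
sessions) moved most treated patients out of the severe/extreme range by the
primary endpoint.  This package turns that severity shift into payer-facing
economics: does the one-time cost of the therapy repay itself through lower
PTSD-related medical spending, fewer premature deaths, and better
quality-adjusted survival?  It is written for health-economics researchers
and payer analysts who want a transparent, scriptable, fully tested
re-implementation of the published decision model rather than a spreadsheet.

## The model

A cohort of 1,000 patients occupies five severity states
(asymptomatic, mild, moderate, severe, extreme), advanced in annual cycles
over a 30-year base-case horizon:

- **Treatment effect.** The treated arm adopts the trial's follow-up
  severity distribution (333 / 262 / 262 / 119 / 24); the control arm stays
  at the intake distribution (0 / 0 / 0 / 714 / 286).  Patients then remain
  in their achieved category — there are no further transitions in the base
  case.
- **Mortality.** Each cycle, a patient in state *s* at age *a* dies with
  probability min(1, RR<sub>s</sub> · q<sub>a</sub>), where q<sub>a</sub> is
  the background life-table death probability and
  RR = (1.00, 1.74, 2.05, 2.51, 2.76) by severity.  The cohort's age
  heterogeneity (normal, mean 41, SD 11.9, truncated to 18–90) is carried as
  one-year strata that age along their own life-table paths.
- **Costs.** The therapy costs $11,537 per patient once, up front
  ($9,828 therapists + $909 screening/lab + $800 tests/pharmacy).  Annual
  medical costs rise with severity ($5,032 … $24,283 per person-year).  The
  achievable saving — the per-capita cost difference between the intake and
  follow-up mixes — is released on a conservative ramp: 0% in year 1, then
  25/50/75/100% in years 2–5.
- **Outcomes.** Discounted (3%/year) net cost and QALYs
  (utility weights 0.90 … 0.37 by severity), undiscounted deaths averted,
  the ICER with dominance handling, and the break-even time at which
  cumulative savings repay the intervention.
- **Uncertainty.** One-way (tornado) analysis over the stated ranges, and a
  10,000-iteration probabilistic sensitivity analysis with moment-matched
  gamma (costs), lognormal (relative risks), beta (utilities, intervention
  cost, discount rate) and truncated-normal (mean age) distributions; a
  scenario analysis lets treated patients relapse one severity category per
  year (5–15%) after year 5.

All inputs live in one flat YAML configuration; the background-mortality
table is a drop-in CSV (`age,qx`).  A bundled synthetic Gompertz life table
anchored at q(41) = 0.0020 makes the package fully self-contained.  See
`docs/methods.md` for conventions, parameter meanings and limitations.

## A worked example

```sh
python examples/base_case.py
```

```text
 horizon         net cost  QALYs gained  deaths averted  verdict
     1 y       11,590,663           244             3.0  $47,469/QALY
    10 y      -45,073,933         2,155            37.0  dominant
    30 y     -116,590,276         4,865           121.7  dominant

break-even at 3.8 years, having already gained 888 QALYs
```

Reading the numbers: if benefits were (implausibly) assumed to vanish after
one year, the therapy would cost about $47,500 per QALY gained — inside the
usual U.S. willingness-to-pay range.  Held for ten or thirty years, it is
*dominant*: the payer saves money (net cost is negative) while the cohort
gains thousands of QALYs.  The up-front outlay is repaid after roughly 3.8
years.  The other scripts in `examples/` demonstrate the tornado analysis,
the probabilistic sensitivity analysis, the progression scenario, the
three- vs two-session regimen comparison, and configuration editing.

The same analyses are available from the shell:

```sh
mdma-cea base-case --horizon 1 --horizon 10 --horizon 30 --out-dir results/
mdma-cea sensitivity --mode psa --iterations 10000 --seed 1 --out-dir results/
```

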
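# Methods

## Model structure

The model is a cohort-level Markov state-transition model with annual
cycles. A cohort enters healthy at age 45 and is followed until death or
age 100 (56 cycles). States:

- `healthy`
- `lr_polyp_undetected`, `hr_polyp_undetected` — undetected low-risk /
  high-risk adenomas (high risk: ≥10 mm or villous/high-grade dysplasia)
- `lr_polyp_refractory`, `hr_polyp_refractory` — lesions already missed
  once by the cohort's screening modality (see *Systematic false
  negatives*)
- `lr_surveillance_1..5`, `hr_surveillance_1..3` — post-polypectomy
  surveillance tunnels, one state per year of the interval (tunnel lengths
  follow the configured intervals; defaults 5 y low-risk, 3 y high-risk)
- `cancer_{local,regional,distant}_{y1,cont}` — diagnosed cancer by SEER
  summary stage, first year vs continuing
- `dead_crc`, `dead_other` — absorbing

Each cycle applies, in order: (1) surveillance-tunnel advancement and any
screening due; (2) natural-history and death transitions; (3) accrual of
life-years and costs. Within the transition step, other-cause death is
applied first, then disease transitions. There is no half-cycle correction;
life-years accrue as start-of-cycle alive mass.

## Disease process and cancer onset

Cancer onset follows the adenoma–carcinoma sequence. The baseline incidence
schedule `inc(a)` gives the annual probability of clinical CRC onset in an
unscreened population. Incident cancers are allocated mostly to the
high-risk-polyp compartment — annual probability
`min(hr_to_cancer · inc(a), 1)` from `hr_polyp_*` states — with a residual
direct pathway `direct_cancer_fraction · inc(a)` from healthy/low-risk
states (default fraction 0.15). This split is what makes polypectomy
durably reduce subsequent incidence, the mechanism behind
colonoscopy-based strategies' incidence benefit. Post-polypectomy
surveillance states carry only the direct-pathway risk.

Symptomatic cancers receive the symptomatic stage distribution; cancer
patients face a stage-specific constant annual cancer-death probability in
competition with other-cause mortality. Survivors remain in the continuing
state (no cure state); age dependence of cancer survival enters through
competing mortality.

## Screening mechanics

At a due screening age, the screened compartments are healthy and the four
undetected-polyp states. For stool/blood tests: lesion-free screenees test
positive with 1 − specificity and receive a follow-up colonoscopy (cost and
complication risk, no state change); polyp holders test positive with the
test's polyp sensitivity, and the follow-up colonoscopy confirms and
removes the polyp with the colonoscopy polyp sensitivity, entering the
surveillance tunnel. For primary colonoscopy, polyps are detected directly
with the age-banded colonoscopy sensitivities. All colonoscopies (primary,
follow-up, surveillance) carry an age-specific complication probability and
complication cost; complications have no mortality.

**Cancer detection as stage shift.** There is no preclinical-cancer dwell
state: the incidence schedule is interpreted as clinical onset. Screening
benefit for cancer is therefore implemented as interception of the
incident-cancer flow in a screening cycle: those cancers receive the stage
distribution `s·screen + (1−s)·symptomatic`, where `s` is the test's cancer
sensitivity (for colonoscopy, its cancer detection rate, with the
complementary interval-cancer rate presenting symptomatically). Earlier
stage means a lower annual cancer-death probability, which is the life-year
benefit of detection.

**Systematic false negatives.** A lesion missed by the cohort's screening
test moves to a refractory compartment that the same test cannot detect
until the lesion progresses (a refractory low-risk polyp that becomes high
risk re-enters the detectable high-risk state, since progression transforms
the lesion). Without this, annual FIT accumulates near-perfect polyp
detection from a 7.6–23.8% per-round sensitivity and overtakes
colonoscopy — inconsistent with the relative strategy performance this
model family reports. Full correlation of repeat results is the simplest
structure consistent with the observed pattern (annual FIT reduces
lifetime incidence least, stool DNA more, colonoscopy most) and mirrors the
systematic-error components of established microsimulation models.

**Persistent adherence.** Each arm is run as a mixture of persistent
sub-cohorts: the 60.6% adherent fraction follows the first-line modality
for life at 100% round adherence, the remainder follows the second-line
modality (LB in the hybrid arm) or no screening. A per-cycle independent
adherence draw would let nearly everyone eventually screen, which is not
the behavior of a fixed-adherence population. Follow-up and surveillance
adherence are 100%.

## Costs and discounting

Unit costs (2022 USD): colonoscopy with/without polypectomy 1366/1119, FIT
52, stool DNA 492, liquid biopsy 949; phase-of-care cancer costs by stage
(first year / continuing / final year): local 42 347 / 3941 / 14 158,
regional 56 019 / 8188 / 25 270, distant 55 705 / 27 586 / 34 464. The
first-year cost is charged on the flow into a first-year cancer state, the
continuing cost per person-year in a continuing state, and the final-year
cost on the transition into cancer death. Symptomatic diagnosis itself is
not charged a separate colonoscopy line item (it is part of cancer care);
positive non-colonoscopy screens are charged their follow-up colonoscopy.

Costs are discounted at 3%/year (year 0 = age 45). Life-years are computed
both discounted and undiscounted; the cost-effectiveness layer uses
**undiscounted** life-years by default, because the ~35.6 life-years from
age 45 that this model family reports is only attainable undiscounted (the
discounted maximum over 55 years is ~27). A config flag
(`policy.discount_lyg`) switches to discounted life-years everywhere.

## Synthetic epidemiology and calibration

The generators replace registry tables with standard parametric forms:

| Input | Form | Default | Rationale |
|---|---|---|---|
| other-cause mortality | Gompertz–Makeham, `h(a)=λ+αe^{β(a−45)}` | λ=8e−4, α=2.1e−3, β=0.088 | life expectancy at 45 ≈ 37 y, US-like |
| baseline CRC incidence | log-linear, plateau at 85 | 1.55e−4 · e^{0.082(a−45)} | ~1.5e−4 at 45 to ~4e−3 at 85; lifetime risk ≈ 5% |
| LR polyp onset | linear in age | 0.0105 + 1.5e−4(a−45) | any-adenoma prevalence in the tens of percent by the 70s |
| prevalence targets | forward integration of onset with nominal progression/exit | LR→HR 0.02/y, HR exit 0.03/y | targets reachable by a cohort that is polyp-free at 45 |
| stage at diagnosis | fixed simplex vectors | symptomatic (0.38, 0.36, 0.26); screen-detected (0.62, 0.28, 0.10) | screen detection shifts stage earlier |
| cancer death | annual probability per stage | (0.016, 0.065, 0.38) before calibration scaling | distant ≫ regional ≫ local |

Calibration fits four free quantities deterministically (fixed starting
points, so re-running is idempotent): a bounded least-squares fit of the
onset scale and LR→HR rate to the polyp-prevalence curves at ages
55/65/75/85 (tolerance ±5 points), then bisection of the HR→cancer
multiplier to 5.2% lifetime incidence (±0.3) and of a joint scale on the
cancer-death probabilities to 1.6% CRC mortality (±0.2), iterated three
outer rounds. Failure raises an error carrying the residual report.

**What the synthetic data does and does not emulate.** It reproduces the
age shapes and aggregate magnitudes (life expectancy, lifetime CRC risk and
mortality, rising polyp prevalence, stage shift) that drive the
cost-effectiveness comparison. It does not reproduce birth-cohort effects,
sex or race/ethnicity differences, real CORI cross-sectional prevalence at
age 45 (the model cohort enters polyp-free), adenoma counts/size
progression, or the serrated pathway. Consequently, passing tests show the
method is implemented correctly and behaves as this model family behaves —
they do not certify the absolute per-person costs, life-years, threshold
prices, or PSA percentages that depend on the unpublished registry tables.

## Sensitivity analyses

- **One-way:** one parameter moved to each bound (negative lower bounds
  clamped at 0), full rerun, ICER of a named strategy pair at each bound;
  entries sortable by range width for a tornado display.
- **Threshold:** bisection of a parameter (typically the LB price) to the
  WTP crossing, after verifying monotonicity on a 5-point grid (refusing
  with diagnostics otherwise); returns the endpoint with a flag when no
  crossing exists. Tolerance 0.5 on the parameter by default.
- **Scenarios:** LB granted polyp sensitivity over an HR × LR grid
  (detected polyps confirmed at follow-up colonoscopy and entering
  surveillance, as for stool tests); low-risk surveillance interval 5/7/10
  years; screening end age 75/85. Each reports whether the preferred
  strategy at the WTP threshold changes.
- **PSA:** beta distributions for probabilities (moment-matched; default
  SD = 10% of the mean), gamma for costs (SD from the ±25% printed ranges
  read as 95% intervals, i.e. range/3.92). Age-specific schedules
  (colonoscopy polyp sensitivity, complication probability/cost) stay at
  base case: no published uncertainty exists for them and a scalar
  multiplier would be invented structure. Natural-history rates stay at
  their calibrated values. Per iteration all six strategies are rerun and
  the optimum per WTP value is the highest net monetary benefit
  (`E·WTP − C`); acceptability curves report the optimal fraction per
  strategy. Fixed seeds give bit-identical results.

## Numerical choices

- Transition rows are asserted row-stochastic to 1e−12; occupancy is
  asserted to sum to 1 (±1e−9) every cycle.
- Frontier ties (equal cost and effectiveness) are strictly dominated
  deterministically by name order; incremental columns for dominated
  strategies are reported against the most costly nondominated strategy
  cheaper than them (the "next least costly nondominated" convention).
- ICERs are kept at full floating precision; printed-table comparisons are
  made on incremental differences, not rounded ICER quotients.
- Default problem sizes: 56 annual cycles, 21 states; the packaged PSA
  uses 500 iterations (a few tens of seconds), with the iteration count a
  config/CLI knob.

## Known limitations

- No preclinical-cancer sojourn: screening detects cancer only in its
  clinical-onset year, so the stage-shift benefit of infrequent tests is
  understated relative to a dwell-time model.
- Full (rather than partial) correlation of repeat test results; no polyp
  regression; at most one modeled lesion per person.
- Complications carry cost only, no mortality or disutility; no QALYs.
- Cohort-level model: no individual memory, so adherence is a persistent
  population split and surveillance is 100% adherent.
- Absolute outputs depend on the synthetic epidemiology; only relative and
  structural results are meaningful for policy reading.
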
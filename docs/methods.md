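# Methods

This note documents the models, conventions and design choices behind
`pipcox`, in the order data flows through the pipeline.

## Date and interval conventions

All dates are whole calendar days. Every interval is closed
`[start, end]`; two intervals *touch* when the second starts the day
after the first ends, and touching intervals merge. This single
convention drives all interval algebra (union, subtraction,
intersection), which is property-tested against brute-force day-set
expansion.

Completed age uses the birthday-anniversary convention; a Feb-29
birthday anniversaries on Mar 1 in non-leap years (deterministic,
matches common civil practice).

## Episode construction (gap days)

Chronic medication reaches the record as consecutive scripts separated
by small refill gaps. Each script's end date is extended by a
medication-specific gap-day allowance chosen from clearance properties
— ASA/ECC 5, platelet-aggregation inhibitors 4, NSAIDs 3, PPIs 3,
oral anticoagulants/corticosteroids/SSRIs 2, with the companion
antiplatelets under the NSAID-combination criterion (START D2C) using
2 — and any two extended scripts of the same patient and class that
overlap or touch merge into one episode. Under the closed-interval
touch rule this extend-then-union formulation is equivalent to
"merge when end and next start are at most gap days apart".

The extension is unconditional: it also applies to the final script of
an episode, so exposure runs gap-days past the last script's end. The
source convention for the episode tail is not documented anywhere we
could check; unconditional extension is the simpler reading of a
per-prescription expiration allowance, and the gap table is
configurable per (criterion, class) for anyone who wants the other
convention.

## Criteria engine

Each of the nine criteria is a conjunction of day-level conditions: a
primary-class episode is active; a companion-class episode is
concurrently active (intersection); a qualifying diagnosis exists on
or before the day (no look-back limit); the completed age is within
bounds; the daily dose exceeds a threshold; the episode has been
continuously active beyond a minimum duration ("NSAID > 3 months"
qualifies from day 91 of continuous coverage).

Decisions worth calling out:

* **Age bounds are inclusive at the printed threshold** (">70" admits
  a 70-year-old, "60–70" includes both ends). The published worked
  example applies both the ">70" and the "60–70" NSAID criteria to a
  70-year-old patient, which forces the inclusive reading. A strict
  mode is available (`strict_age_bounds`).
* **Age conditions are dynamic**: intervals split at birthday
  anniversaries, so a criterion can switch on mid-episode. Evaluating
  at prescription start instead is not supported; the dynamic reading
  is the natural one for day-resolved exposure.
* **History code sets are configurable defaults** (peptic ulcer
  D85/D86, bleeding disorder B83, gout T92) because the source
  guideline's full ICPC lists are not published.
* **STOPP E5's allopurinol clause** ("without contraindication or
  proven ineffectiveness for allopurinol") is not computable from
  prescriptions and diagnoses alone; the implementation is NSAID use
  > 90 continuous days plus gout history. This is a documented
  simplification.
* **Dose thresholds** (STOPP A9: ASA > 160 mg/day, carbasalate
  calcium > 200 mg/day) are applied per prescription before merging,
  keyed by ATC prefix, so merged supra-threshold episodes never mix in
  low-dose scripts.
* The **ATC→class map** ships as an overridable default; plain ASA
  (B01AC06, N02BA01) and carbasalate calcium (B01AC08) are carved out
  of the broader antiplatelet group B01AC by longest-prefix matching.

Part-1 (nonadherence) semantics subtract PPI-covered days from START
intervals; part-2 keeps the medication intervals as-is and returns the
PPI intervals separately for the interaction model. The identity
`part1 = part2_meds − PPI` is asserted on random cohorts.

## Bleeding detection

The ICPC channel takes D14/D15/D85/D86, one event per patient-day.
The free-text channel matches an anchor stem ("bloed") plus a
digestive-context term on lowercase, diacritic-stripped text, accepts
the note only when its attached code is non-specific (default
{A99, D99} or absent) and not in an exclusion set of specific other
diagnoses (default {R06, U06, W03}), both configurable — the source
keyword and code lists are not published, so the defaults are the
package's own. Events from both channels are unioned (ICPC wins on a
same-day collision) and events of one patient closer than 30 days are
treated as the same bleeding. The 30-day distinctness window is a
package choice (configurable); recurrent bleedings beyond it keep the
patient at risk — no washout is applied.

## Time-splitting and the model dataset

The time axis is days since the study start, with delayed entry: a
patient contributes to risk sets only from max(study start, 65th
birthday) to their exit. Follow-up is cut at every exposure start,
every exposure end + 1, and every event day; each segment becomes one
`(t_start, t_stop]` row with event = 1 on rows ending at a bleeding.
A participant with no exposure and no event yields exactly one
sequence; a full-window patient whose exposure flipped daily could
reach the theoretical maximum of window-days − 1 = 2921 sequences.

For model fitting, rows are additionally cut at birthday anniversaries
(`split_at_birthdays=True` in the assembly path). Age in completed
years is then exactly constant within every row, making the age
covariate genuinely time-updated. This matters: with age frozen at
row start, the single long row of a never-exposed patient understates
their age by years, inflating the apparent baseline hazard and biasing
the exposure coefficient noticeably downward (about −5% on the
composite effect in our calibration runs). The refinement adds rows
but leaves person-time, events and — by split-invariance of the
partial likelihood — everything else unchanged.

Events on an exposure boundary take the exposure status of the event
day itself (intervals include their end day).

## Cox fitting

`pipcox._coxfit` maximizes the Efron partial likelihood (day-grain
data guarantees tied event times) by damped Newton iteration with
analytic gradient and Hessian, supporting left truncation. Variance
comes in two flavours: model-based (inverse information) and the
cluster-robust sandwich `A⁻¹ B A⁻¹`, where `B` sums Therneau score
residuals within participant before forming outer products — all
sequences of one participant are one correlated unit. Coefficients,
naive and robust standard errors are cross-validated in the tests
against an independent brute-force likelihood maximization, against
`lifelines` point estimates, and against frozen
`R survival::coxph(..., cluster(id), ties="efron")` reference values.
(The fitter is in-package because the robust variance of available
Python implementations disagrees with the R reference under delayed
entry; see the repository history for the comparison.)

Reported quantities satisfy exactly: HR = exp(b), CI = exp(b ±
1.959964·se), p from the two-sided Wald test on the robust SE, α =
0.05. A coefficient diverging past |b| > 15, or a failed Newton
convergence, flags monotone likelihood; the affected hazard ratio is
reported as non-estimable (NaN) rather than as a huge number, and the
battery runner records the row and continues.

The analysis battery mirrors the study design: all criteria combined,
STARTs combined, STOPPs combined (age/sex adjustment only), each of
the nine criteria in a multivariable and a confounder-adjusted form
(the remaining criteria merged into one `pip_other` covariate), the
six part-2 medication models with their PPI-interaction variants, and
sensitivity fits on the subpopulation with at least one bleeding.
In the interaction model `H(t) = h0·exp(b1·meds + b2·PPI + b3·age +
b4·sex + b5·meds·PPI)`, the medication HR without PPI is `exp(b1)` and
with PPI `exp(b1 + b5)`; the identity is tested against a refit on the
stratified recoding. (The published formula for this model mixes two
symbols for the medication term; we use the part-2 medication
indicator as the main effect, consistent with the part-2 exposure
definition.)

## Synthetic cohorts

The generator emulates the study population: an 8-year window
(2007-01-01 to 2014-12-31); entry at the study start or the 65th
birthday (age at study start uniform on [57, 90], so the median age in
care lands near the low 70s); 59% female; a combined death/leave exit
hazard of 0.08/year. Chronic drugs are issued as 1 + Poisson scripts
of uniform 14–90 days with uniform 0–10 day refill gaps, so the
gap-day merge rule is exercised in both directions. Default class
prevalences are set so that ≈12% of patients acquire at least one
nonadherence record and ≈19% ever receive a PPI, with a median record
duration around 38 days — matching the descriptive shape of the
population the analysis was designed for. The declared target
(`expected_pip_patient_fraction = 0.12`) is Monte-Carlo-checked to
±5 percentage points.

Bleedings are drawn at day resolution: each in-care day is an
independent Bernoulli with `p = 1 − exp(−λ(t))`,
`λ(t) = λ0·exp(b_exp·PIP(t) + b_ppi·PPI(t) + b_age·(age−75) +
b_male·male)`. The default planted composite effect is `b_exp =
log 5.45`; `b_age = 0.05`/year and `b_male = 0.4` are modest,
plausible values, and `b_ppi = 0` by default. The age effect is
centred at 75 so `λ0` is the hazard of a typical unexposed patient.
The default `λ0 = 2·10⁻⁵`/day is deliberately far above the empirical
GI-bleeding rate of the population the generator emulates: at desk
scale (thousands rather than tens of thousands of patients) it yields
enough events for stable fits, and realism is one number away.
Successive events of one patient are at least 30 days apart (matching
the detector's distinctness window); a bleeding written as D85/D86
creates peptic-ulcer history, switching the ulcer-history criteria on
from the event day onward exactly as the rule engine sees it post hoc.
A configured fraction (0.13) of events is written only as a free-text
note under a non-specific code; distractor notes (bleeding keywords
with a specific non-GI code) and benign notes are planted to exercise
the detector's exclusion rules.

Ground-truth exposure labels are computed by an independent day-grid
(boolean array) implementation of the same rules the interval engine
applies; exact agreement between the two code paths is asserted on
random cohorts.

What the generator does *not* model: realistic clinical prose,
over-the-counter medication (invisible to prescription records),
dose tapering or stockpiling, competing risks beyond censoring, and
confounders such as smoking or alcohol. Passing tests therefore
demonstrate that the pipeline recovers effects *under the stated
generative model*, not that the rule configurations capture every
real-world prescribing pattern.

## Calibration studies

`pipcox.calibration` measures the pipeline's operating
characteristics end to end. The calibration configuration enriches
exposure (NSAID/ASA user probabilities 0.5/0.3 with longer episodes)
and raises `λ0` to 5·10⁻⁵/day so each 2,000-patient replicate carries
a few hundred events with a usefully large exposed share; these sizes
were chosen once, by power reasoning, so that the Wald normal
approximation is informative. Replicates use ground-truth labels for
the exposure records — provably identical to engine output by the
exactness test — and warm-start the concave likelihood at the planted
values (a speed-only choice). Measured at these sizes: relative bias
of the mean composite coefficient ≈ +0.5%, 95% CI coverage 95.0%
(200 replicates), and a null rejection rate of 6.8% over 500
replicates — slightly above the nominal 5%, as expected for Wald
tests with a moderate number of exposed events, and within the
5% ± 2% acceptance band.

## Known limitations

* Free-text detection is deterministic keyword matching; no negation
  handling, no manual-inspection step.
* The dose field must arrive pre-resolved as mg/day; dispensing-text
  parsing is out of scope.
* Monotone-likelihood fits are flagged, not corrected (no Firth
  penalty).
* No multiple-testing correction across the battery (by design,
  matching the analysis plan the package implements).
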
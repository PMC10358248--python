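# Methods

This note documents the reconstruction rules, the simulator's
data-generating process, the numerical conventions, and the design choices
made where the problem was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The reconstruction model

Administrative claims contain no progression assessments, so "PFS" here is
a *prescription-defined proxy*: treatment episodes are cut purely from
dated prescriptions, the drug dictionary, death and follow-up dates. The
pipeline is deterministic given its inputs and invariant to input row
order.

**Cohort criteria and order.** Criteria run in patient-flow order:
definitive C25x diagnosis → lookback claim (strictly >28 days before the
first confirmed diagnosis; any record type counts, including
diagnosis-only records) → no surgery/radiotherapy on/after diagnosis →
indicated chemotherapy within 60 days (both ends inclusive) → diagnosis on
or after 2015-01-01. The first failing criterion is the single recorded
exclusion reason, so attrition counts are non-increasing by construction.
Surgery/radiotherapy detection is by configurable claim-code sets
(defaults {50, 54} and {81}); the source fee-schedule masters are not
public, so these are parameters, not facts. "On or after the diagnosis
date" includes the diagnosis day itself.

**Lines and labels.** A line's components are every pancreatic-indicated
anticancer drug *first administered* within 28 days of the line's anchor.
Consequences worth knowing:

* A true clinical switch within 28 days of initiation is absorbed into the
  first-line component set — it is unidentifiable under this definition,
  by design.
* Label precedence is GnP before FFX: nab-paclitaxel is the more specific
  marker, so a set with nab-paclitaxel plus FFX components is GnP.
  Modified FOLFIRINOX is not distinguished from FFX. Supportive-care
  drugs never enter a component set.
* Some transitions are structurally invisible: a second line whose drug
  set is contained in the first-line set (e.g. gemcitabine monotherapy
  after GnP) is, by the restart rule, a continuation of the first line.
  The simulator's config validator rejects such transitions rather than
  planting unrecoverable truth.

**Episode ends.** The treatment end of a line is the per-drug maximum of:
last administration date (parenteral) or last fill date +
⌊quantity / standard daily dose⌋ days (oral), capped at last follow-up.
The day-supply quotient is floored by default (partial days do not extend
treatment); `day_supply_rounding="half_up"` is available. The quantity
interpretation — dispensed quantity divided by standard daily dose — is
the only dimensionally coherent reading of the day-supply rule and is
exposed as a config toggle (`oral_extended_end=False` gives the literal
last-prescription-date variant). If a switch drug appears before the
computed first-line end, 1stPFS is truncated at the switch and 1stPD has
zero length; zero-length episodes are kept (they contribute no cost
months), so every first-line patient routes to exactly one of
{1stPD + 2ndPFS, TC}.

**Cost months.** A month is a 30-day half-open window anchored at the
episode start; calendar-month anchoring was rejected because episodes
start on arbitrary dates. A patient contributes month *k* only when the
full window fits inside the episode — this operationalizes the
at-least-one-month rule and produces the characteristic shrinking *N* by
month — and at most six months count per episode. Episodes with a
successor (1stPFS, 1stPD) absorb claims over [start, end) and terminal
episodes (TC, 2ndPFS, OS) over [start, end], so no claim is double-counted
across the mutually exclusive episodes; OS, which overlaps everything, is
excluded from monthly cells and appears only in cumulative reference
totals. Costs are integer JPY end to end and converted to USD (114.59
JPY/USD, April 2019) only at summary time; sample SD uses n−1 and is 0 by
convention for singleton cells. Category shares are pooled ratios
(Σcategory/Σtotal × 100 per regimen-month), reported for the first three
months of first-line treatment. Printed percentages are rounded half-up
to one decimal; banker's rounding would differ on ties. The overall
second-line/BSC split uses the four recommended regimens (FFX, GnP, GEM,
S-1) as denominator, excluding "other" — the only arithmetic consistent
with per-arm counts.

## The simulator

Each patient draws from an independent generator stream keyed by
(seed, patient index), so identical configs are byte-reproducible and
growing the cohort never reshuffles earlier patients.

Trajectory: index diagnosis (uniform over 2015-01 to mid-2017; 2014 when a
pre-2015 violation is planted) → chemotherapy start 3–30 days later
(70–150 for planted late starters) → first-line regimen from the
configured mix, emitted as cycle-dated prescriptions (FFX every 14 days;
GnP/GEM weekly; S-1 oral fills every 28 days at 4 units/day × 28 days;
gemcitabine+erlotinib for "other") with a geometric number of cycles, so
episode ends always fall on prescription-derived dates. Default mean
first-line spans are 90–115 days by regimen; default mix
(GnP .407, GEM .244, S-1 .213, FFX .071, other .065), per-arm second-line
probabilities (1 − BSC rates: .517/.348/.297/.195) and second-line
destination rows follow the observed Japanese DPC practice pattern the
package is designed around. With probability .15 a line contains a
restart gap (35–60 days) that must not split it. Switch dates fall at
least one day after the first-line end and, by construction, outside the
28-day combination window (see identifiability above). Death (p = .6)
coincides with the last follow-up date; otherwise the patient is censored
there.

Costs: for every full 30-day window of each episode, each category draws
`share × scale × LogNormal(0, σ=0.35)` JPY (scales 137k–780k JPY/month by
regimen, ordered S-1 < GEM < other < FFX < GnP; category shares
medicines/hospitalization-dominated for FFX/GnP, hospitalization-led for
GEM/S-1), multiplied by 1.6 in each episode's first month
(admission-heavy starts). Draws are split into 1–2 claim lines dated
inside the window, with one line pinned to the window start so episode
starts are observable record dates; a residual-tail claim is dated
strictly before the episode end so it can never bleed into a successor's
first month. Distractor records (non-cancer diagnoses, supportive
prescriptions, pre-treatment claims) are dated outside every cost window.
Ground truth records verdict + reason, both line labels, switch date, all
episode boundaries, per-window per-category costs, and per-episode totals.

What the simulator does **not** emulate — and therefore what passing
recovery tests do not show about real data: fee-schedule price structure
and DPC bundling, multi-hospital fragmentation, dose reductions and
cycle delays, diagnosis-code noise on C25 itself, truly early switches
(inside the combination window), and clinical correlation between
characteristics (age, stage) and treatment choice; the characteristics
table fields are pass-through nuisance columns.

## Problem sizes and defaults in the verification suite

Recovery is checked at n=2000 patients (exact match required for
verdicts, labels, switch dates, boundaries and monthly cells); the
day-resolution scanner cross-check runs 50 patients × 20 seeds; category
share recovery uses n=500 with a planted 50/40 medicines/hospitalization
mix and a ±2-percentage-point band; mix recovery uses ±3 binomial SE at
n=2000. These sizes give comfortable statistical resolution while keeping
the whole suite around a minute on one core.

## Known limitations

* The episode grammar stops at the second line; third-line therapy is
  out of scope, as is survival modelling or cost-effectiveness analysis.
* Cohort stratification by cancer stage is not performed (stage fields
  are descriptive pass-through only).
* Per-regimen cost estimation for second-line therapy is not provided;
  monthly tables pool second-line regimens.
* The category-share horizon (3 months) and cost horizon (6 months) are
  conventions of the reporting layer, configurable but not inferred from
  data.
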
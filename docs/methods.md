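# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Conventions

Dates are ISO-8601 externally; internally every window is an inclusive
integer day offset from the member's index date. The pre-index window is
days [−360, −1], the post-index window days [0, +359] (the index date
belongs to the post period). "Within k days" means a difference ≤ k whole
days. ICD-9-CM codes match by prefix on the dot-stripped code ("493"
matches "49390" and "493.90"), because claims extracts vary in decimal
formatting. Annualization uses a 360-day year throughout, consistent with
the 360-day observation windows. The shipped NDC/procedure dictionaries
contain synthetic but structurally valid codes (real DMT code lists are
licensed); all code sets are editable YAML.

## Cohort selection

The index event is the first fingolimod/GA claim inside the index window
(default 2010-10-01..2012-03-31) whose nearest preceding IFN claim is at
most 90 days earlier, measured fill date to fill date (the criterion speaks
of "a claim for" the prior therapy, not of exposure end). Only this first
switch is assessed. Criteria apply in a fixed order (switch evidence,
continuous enrollment, MS diagnosis within the study window, adult age,
then the exclusions); because they are conjunctive, reordering changes
per-row attrition counts but never the final cohort, and the attrition
table conserves the initial count exactly. Choices worth flagging:

* Continuous enrollment tolerates zero gap days; purely administrative
  1-day boundary joins between spans are merged at load time.
* The "missing days supply" exclusion is operationalized as any
  index-therapy fill from the index date onward with missing **or zero**
  days supply — the minimal deterministic reading of an indicative gap.
* Age at index is index year − birth year (claims extracts carry year of
  birth only).
* The MS-diagnosis window is [−360, +359], matching the post window's upper
  bound; whether day +360 itself should count is ambiguous in the design,
  and the bound is configurable.

## Relapse detection

Inpatient events require a *primary* diagnosis of 340; outpatient events
require a 340 diagnosis in any position plus an oral corticosteroid fill or
IV corticosteroid administration in the steroid window. The steroid window
is directional — [visit, visit+7] — on the reasoning that treatment follows
assessment; a symmetric ±7 switch exists. A same-day claim with a primary
exclusionary diagnosis (default prefixes 493 asthma, 274 gout, 714
rheumatoid arthritis, 364 uveitis; editable, since the design names these
conditions non-exhaustively) suppresses the event.

Collapsing uses a fixed anchor: the earliest unassigned event opens an
episode and everything within 30 days of *that anchor* joins it. A rolling
chain mode is available but not default, because chains can merge
unboundedly long spans. An episode is inpatient if any constituent event
is; both-kind flags are kept so inpatient/outpatient tallies that do not
sum to 100% remain reproducible. Counting "while persistent" keeps episodes
with onset on or before the persistence end day.

## Persistence

Fills accumulate coverage end-to-end (stockpiling; a no-stockpile switch
truncates overlaps), and clinic administrations cover a fixed 28 days each
(procedure claims carry no days supply). The runout day is the first
uncovered day; discontinuation triggers when the next fill arrives **at
least** `gap_days` (60) after runout, or when no fill arrives and the
horizon is ≥ 60 days past runout, with persistence ending at runout — the
unexposed gap is not credited with follow-up time. A claim for a different
DMT of interest before the gap completes ends persistence as a switch on
the day before the claim. Days persistent = the count of covered days, so
the last persistent day is index + days − 1. A member whose exposure runs
out within 60 days of the horizon can no longer exhibit a qualifying gap
and is censored at the horizon with 360 days — an unavoidable edge of the
gap rule, shared with the original design. Persistence never re-opens
after a qualifying end (first-event precedence); restarts within the
horizon are out of scope.

## Propensity model and matching

The default model is the fixed final covariate list (age, gender, region,
plan type, prescriber specialty, Charlson score, dalfampridine use, relapse
within 90 days pre-index, pre-index total costs, numbness/fatigue/bowel
symptoms, depression, diabetes), fitted by ordinary logistic ML; a forward
stepwise mode (likelihood-ratio entry/stay p = 0.15 — the design calls for
stepwise selection but states no thresholds) is secondary. Costs enter in units of
$10,000 for optimizer conditioning. Constant design columns are dropped
with a warning; separation falls back to an L1-penalized fit, flagged.

Matching is greedy nearest-neighbor without replacement on the probability
scale within pre-index relapse-count strata (0, 1, 2, ≥3): "random"
matching is realized as a seeded random processing order of treated
members; ties among equidistant controls break to the lowest member id so
a seed fully determines the pairing. The caliper defaults to 0.01 in
fitted probability (the design offers ±0.01 only as an example; the value
is config and logged per run). Unmatched members on both sides are
reported, never dropped silently. Exact stratification forces identical
pre-index relapse-count histograms across the matched arms by
construction. Balance is summarized by standardized mean differences with
the pooled-variance denominator (proportion-based for binaries).

## Outcome models

Both effect models are GEEs clustered on the matched pair with an
exchangeable working correlation and robust (sandwich) variances — the
pair is the only disclosed cluster structure. The logistic model includes
log(years persistent) as an offset exactly as specified, although offsets
in logit models are unusual (the "OR" then mixes exposure-time
normalization into the link); a no-offset variant is emitted alongside for
transparency. The negative-binomial model profiles the NB2 dispersion α by
maximum likelihood on the pooled data and then holds it fixed inside the
GEE (the design leaves dispersion handling open); α → 0 recovers the
Poisson model. Model-based ARRs are the predicted rates at one year
(offset 0), covariates at their means. Members with zero persistent days
would make the offset undefined and are excluded from the models with a
logged count. Crude ARRs are total episodes over total person-time.
Kaplan–Meier curves censor at discontinuation or the horizon; treating
discontinuation as a competing risk rather than censoring is a known
caveat of the design. Sensitivity refits add the seven symptom covariates
excluded from matching, dropping degenerate columns with a warning.

## Synthetic claims generator

The generator emulates the study conditions: every member has an IFN
history ending 1–85 days before a drawn index date (uniform in the index
window), enrollment covering the full study window with a 30-day pad,
30-day index-DMT fills, and relapses from a homogeneous Poisson process
with per-member gamma frailty (shape 1.5, mean 1), making counts
marginally negative-binomial — the outcome model is correctly specified
under the defaults. Defaults are the study's observed conditions:
pre-index rate 0.47/360 days; GA post-index rate 0.51/360 days with a true
fingolimod/GA rate ratio of 0.38; per-arm exponential stop-time hazards
calibrated so that exposure survival at day 300 equals the reported
persistence proportions (0.735/0.629 — with 30-day fills and the 60-day
gap rule, stopping after day 300 is indistinguishable from persisting to
the horizon); 10% of relapses inpatient (a loose calibration anchored
only to small observed counts); steroid capture probability 0.95 for
outpatient relapses, 80% oral / 20% IV, delay uniform on 0–7 days.
Treatment assignment is logistic in the pre-index relapse count, recent
relapse, and several baseline covariates (prevalences from the published
baseline table), giving genuine confounding through the frailty channel
that stratified matching must remove. Noise processes (non-MS visits,
MS visits without steroids, steroid fills without visits) default to
2.0/0.5/0.1 per 360 days. One routine MS visit per member guarantees the
MS-diagnosis criterion and is placed more than 8 days from every true
relapse so it can never manufacture a detected event. All randomness flows
from one seed through per-member spawned substreams, so growing the
population never perturbs existing members.

What the generator does **not** emulate: real NDC/procedure coding
variety, pricing realism, seasonal or geographic structure, informative
censoring (stop times are independent of frailty), covariate effects on
the outcome other than through assignment, or diagnostic miscoding beyond
the simple noise processes. Passing tests therefore demonstrate the
pipeline's correctness and its operating characteristics under the stated
model, not performance on any real database.

## Verification strategy and numerical notes

Every nontrivial algorithm is checked against an independent brute-force
oracle on randomized inputs: 30-day collapsing against a literal day-scan,
runout/gap persistence against a per-day pill-stock simulation, matching
against exhaustive nearest search, the log-rank statistic against direct
tabulation, and GEE against ordinary ML in the one-member-per-cluster
limit. On noise-free bundles the detector reproduces the generator's
episodes exactly. Recovery simulations run the full pipeline at about 500
matched pairs (1300 members): across 200 replicates the mean estimated
rate ratio sits a few percent above the true 0.38 — detected rates are
attenuated slightly more in the higher-rate arm because 30-day collapsing
merges proportionally more of its events, a real property of claims-based
relapse measures — and robust-CI coverage stays near nominal; under a true
rate ratio of 1 the rejection rate is near the 5% level. Replicate counts
(200/300) and the 1300-member population are the package's standard
simulation sizes. Tie-breaks are deterministic everywhere (lowest id;
stable sorts); probabilities are clipped to (0, 1) before matching; NB
dispersion is floored at 1e-8.
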
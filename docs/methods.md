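# Methods

## Data model

A registry bundle is four tables linked by `patient_id`:

* **episodes** (the CCM table): one row per *patient instance* — an
  eligibility-to-end record. `eligibility_date` and `end_date` are
  required by the registry's rules; `start_date` (the date a care
  coordinator offered the intervention) may be missing. The composite
  episode key is `(patient_id, eligibility_date, start_date)`, with a
  missing start date encoded by an `NA` sentinel so not-approached
  instances still carry a well-defined key.
* **contacts**: coordinator contact log — contact date and minutes spent.
  Rows with a missing contact date are retained but excluded from all
  frequency/duration computations.
* **questionnaires**: instrument responses (PHQ-9 with nine 0–3 items and
  a total, GAD-7, MDQ, AUDIT) with a recording date.
* **demographics**: one row per patient, including consent,
  bipolar-history and depression-diagnosis flags.

All dates are timezone-free calendar dates; durations are whole days
(episodes) or whole minutes (contacts). Delimited-text I/O defaults to
comma-separated ISO-8601, both overridable through `Dialect`. Loading
never drops rows; unparseable dates become missing values and are logged.

**Contact attribution.** A contact belongs to an episode when its date
lies in the closed interval `[eligibility_date, end_date]` of that
episode. When several episodes of one patient cover the date, the contact
goes to the episode with the latest eligibility date not after it (ties
broken by smallest episode id). The closed upper bound means a contact on
the end date still counts. Generated episodes of one patient never
overlap, so attribution on synthetic data is unambiguous; on real data the
tie-break is a documented assumption. Questionnaires are attributed by the
same rule on their recording date.

## Data-quality engine

Rules are declarative records (family, dimensions, target table/columns,
parameters, repair policy) executed in a fixed family order:

1. attribute-domain, 2. relational-integrity, 3. historical-data,
4. state-dependent, 5. attribute-dependency.

Domain rules run first so downstream rules see normalised values: an
out-of-domain PHQ-9 item is blanked (set-to-missing is the default policy
for out-of-domain values; exclusion is the alternative) before the
total-vs-sum rule runs, which then skips the now-incomplete row instead of
double-flagging it. The total-vs-sum repair policy is configurable with
default *recompute from items*. The free-text employment dictionary ships
with the two canonical clinic phrasings ("I am employed" → yes, "I am
looking for a job" → no) and is user-extensible; unknown free text is set
to missing with a flag.

Each rule carries an explicit dimension subset, and report dimension
totals are exact integer sums over rules tagged with that dimension.
Violations with actions in {normalized, set_missing, recomputed} are
*repairs*; a second assessment of cleaned output performs zero repairs
(flag-only findings such as duplicate keys are re-reported, since nothing
was changed). Timeliness is deliberately out of scope; the engine is
purely declarative — no statistical outlier detection.

The "every enrolled patient has a contact date" rule is scoped to
episodes whose status was *recorded* as enrolled. Without a recorded flag,
a start-date episode with zero contacts is exactly what the classifier
labels opt-out, so treating it as a data error would contradict the cohort
builder. For the same reason, all questionnaire rows are treated as intake
instruments for the before-enrollment rule.

## Missing data

Two procedures, applied in order, each emitting a report whose
dropped/recovered/untouched sets partition the episodes examined:

1. **Complete-case drop** removes episodes with a start date and no end
   date. The unit is the episode, not the patient — a patient's other
   episodes survive. The mechanism annotation (MCAR) is a narrative label
   attached to the report, never inferred statistically.
2. **Start-date recovery**: for each remaining episode with a missing
   start date, compute eligibility-time `end − eligibility`; if positive
   and attributable dated contacts exist, the earliest contact date
   becomes the start date with provenance `recovered`. By construction the
   recovered date lies in `[eligibility_date, end_date]`, and adding an
   earlier in-window contact can only move it earlier. Two same-day
   earliest contacts are a single candidate date, so no tie-break is
   needed. No model-based imputation is attempted.

## Status classification and eligibility

Classification is a pure function of (episode, metrics, start-date
provenance). Precedence: recorded status > derived. The derivations:

| condition (after recovery) | status | provenance |
|---|---|---|
| start present, frequency > 0 and total time > 0 | enrolled | derived_A |
| start present, frequency = 0 or total time = 0 | opt_out | derived_A |
| start recovered from contacts | enrolled | derived_B_recovered |
| start still missing | not_approached | derived_B_unapproached |

The disjunction is taken literally: positive frequency with all-zero
minutes (legal, since the per-contact minimum is 0) classifies as opt-out.

Eligibility is evaluated per episode in fixed order — research consent
first (a non-consenting episode gets no further reasons), then the
clinical criteria: age ≥ 18 at the eligibility date (age is anchored at
eligibility, since no other anchor is defined), no bipolar history, a
depression diagnosis, and baseline PHQ-9 ≥ 10, where baseline is the
latest PHQ-9 on or before the eligibility date and a missing baseline
fails the criterion. Approached (start-date) episodes below the PHQ-9
threshold are retained under the provider-discretion override, on by
default. The ≥ 2 PHQ-9 requirement belongs only to the cross-sectional
study pathway and is a config toggle, off by default.

PHQ-9 severity bands: ≤5, >5 <10, ≥10 <15, ≥15 <20, ≥20, missing —
exhaustive and mutually exclusive over 0–27.

## Index dates and windows

Six months is encoded as 183 days (configurable); all windows are
half-open `[index, index + w)`, so a record dated exactly at the index
falls in the outcome window. The shifted-eligibility lag is the arithmetic
mean of `start − eligibility` over enrolled episodes, rounded to the
nearest whole day. "First enrolled episode" means minimum start date, ties
broken by minimum eligibility date then episode id. For comparison
patients with several eligibility dates under the enrollment-linked and
shifted strategies, the default pick is the first, exposed as a switch
(`comparison_pick="last"`), since no single choice is canonical.

Within a window, multi-status patients resolve by precedence
enrolled > opt-out > not-approached; an enrolled episode must *start*
in-window, and completes if its end date precedes the window close.
Enrollment is intent-to-treat: dropout or remission inside the episode
does not change membership. Enlarging the window can promote a patient
from incomplete to completed enrollment, never the reverse.

## Synthetic registry generator

The generator emulates the structural and statistical features the
pipeline consumes, with defaults matching the registry profile it is
modelled on: status mixture 44.30 / 33.30 / 22.40, 23.42% missing start
dates, eligibility dates spanning 2008-03-03 to 2018-05-17, activation
times capped at 1,263 days, eligibility-times at 900 days, contact counts
at 123 and per-contact minutes at 990. It does **not** model clinical
trajectories — no symptom dynamics, remission curves, or correlation
between severity and engagement — so passing tests demonstrate pipeline
correctness on structurally realistic data, not clinical realism.

Key mechanics:

* Two allocation modes: *exact* (largest-remainder quotas, shuffled) for
  planted-truth tests, and *stochastic* (independent per-episode draws)
  for statistical-fidelity checks.
* The overall missing-start share is met by blanking the start dates of
  `round(rate·n) − n_not_approached` enrolled episodes ("recoverable");
  each keeps a contact exactly on its true start date, so recovery is
  exact and the emitted missing-start share equals the configured rate.
  At the full profile (n = 15,576) this yields ~150–160 recoverable
  instances.
* Missing-end episodes (the complete-case-drop targets) are generated *in
  addition to* the configured episode count, so dropping them restores
  the planted mixture exactly.
* Episodes of one patient are laid out with ≥ 120 days between
  consecutive eligibility dates, guaranteeing non-overlap.
* Ages are truncated-normal (mean 41.3, SD 16.2, clipped to 19–85) at the
  first eligibility date; demographic category frequencies default to the
  enrolled-column profile (71.5% female, 92% White, etc.).
* Where only min/max are known, distribution shapes are pragmatic:
  Poisson(+1) contact counts, log-normal minutes and durations — all
  clipped to the configured caps. These choices are arbitrary and
  isolated in the config.
* A single root seed spawns independent substreams per table, so the same
  (config, seed) reproduces output byte for byte.

Error injection corrupts a clean bundle with a configured number of
violations per kind (out-of-domain PHQ-9 item, free-text employment
answer, duplicate composite key, end-before-start inversion, blanked
eligibility date, total≠sum) and records each in a ledger with the
original value. Injections never collide on a cell, and the PHQ-9 item
and total/sum kinds use disjoint rows so each stays independently
detectable after domain repairs.

## Problem sizes and tolerances

The test suite validates planted-error recall and false positives on a
2,000-episode bundle (60 injections), exact status recovery at 5,000
episodes, brute-force oracle equivalence of metrics and window cohorts on
200 bundles of ≤ 20 episodes, and stochastic marginals at the full
n = 15,576 profile over three seeds with a ±1 percentage-point band —
sizes chosen so the whole suite runs in well under a minute per check
while keeping binomial noise at n = 15,576 (≈ 0.4 points SD) comfortably
inside the band. Property-based tests (hypothesis) are derandomised for
reproducibility.

## Known limitations

* Free-text normalisation is dictionary lookup only; unmapped text is
  flagged to missing rather than fuzzily matched.
* The eligibility filter reads one demographics row per patient; if
  duplicates exist (themselves a uniqueness violation) the first is used.
* MCAR/MAR/MNAR labels are annotations, not inferences; no statistical
  missingness tests are run.
* Longitudinal multi-window designs and outcome-effectiveness estimation
  (remission, ED visits, hospitalisation) are out of scope; the window
  builder stops at cohort membership.
* The printed internal counts of the registry the profile emulates do not
  all reconcile with each other; the generator reproduces its stated
  marginal rates, not its exact cross-tabulations.
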
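# regforge

Turn clinically collected patient-registry data into research-ready
datasets.

Patient-centered registries — such as the collaborative-care (CCM)
depression registries kept by primary-care practices — are built for care
management, not research. Before their data can answer a retrospective
research question, four things have to happen: record-level data-quality
errors must be found and repaired, missing key dates must be handled,
every patient instance must be classified into a cohort status, and a
defensible index date with observation/outcome windows must be chosen.
`regforge` implements that pipeline end to end for a registry modelled as
four linked tables (CCM episodes, contact log, questionnaires,
demographics), and ships a synthetic-registry generator with planted
ground truth so every stage can be validated without access to protected
health data.

It is aimed at biostatisticians and clinical informaticists preparing
EHR-adjacent registry extracts for cross-sectional or cohort studies.

## What it computes

**Data quality.** A declarative rule engine covering five rule families —
attribute-domain constraints (PHQ-9 items in 0–3, free-text employment
answers normalised to yes/no), relational integrity (composite episode key
`(patient_id, eligibility_date, start_date)` uniqueness, orphan rows),
historical-data rules (birth date before all events, date ordering),
state-dependent rules (an end date implies an eligibility date; intake
questionnaires recorded on or before enrollment), and attribute-dependency
rules (PHQ-9 total = Σ items) — across the accuracy, completeness,
consistency, validity and uniqueness dimensions. Every repair is traceable
to one violation; re-running on cleaned output repairs nothing.

**Missing data.** Episodes with a start date but no end date are dropped
(complete-case). For an episode with a missing start date, if the
eligibility-time `end − eligibility > 0` and attributable contacts exist
in `[eligibility, end]`, the earliest contact date becomes the start date.

**Derived metrics.** Per episode: activation-time
`SE_Time = end − start` (days), eligibility-time `end − eligibility` (when
the start is missing), `CE_Time = end − first contact` (when the start was
recovered), contact frequency and total time spent (minutes).

**Cohort status.** Each eligible episode is exactly one of *enrolled*,
*opt-out*, *not-approached*: a recorded status wins; otherwise a start
date with contact frequency > 0 and total time > 0 means enrolled, a start
date without engagement means opt-out, a recovered start date means
enrolled, and a still-missing start date means not-approached.

**Windows.** Three index-date strategies (first eligibility,
enrollment-linked intent-to-treat, eligibility shifted by the mean
eligibility-to-enrollment lag) and, under first-eligibility, the four
6-month (183-day, half-open) cross-sectional cohorts: completed
enrollment, incomplete enrollment, opt-out, not-approached.

## Worked example

```python
import regforge as rf

cfg = rf.GeneratorConfig(n_patients=900, n_episodes=1000, missing_end_rate=0.005)
bundle, truth = rf.generate_registry(cfg, seed=11)

corrupted, ledger = rf.inject_errors(bundle, rf.ErrorConfig.uniform(2), seed=11)
report, repaired = rf.run_quality_assessment(corrupted)
print("violations:", report.n_violations, "repairs:", report.n_repairs)
print("by family:", report.family_counts)

cleaned, drop_rep, rec_rep = rf.clean_bundle(repaired)
print("dropped (start without end):", drop_rep.n_dropped)
print("start dates recovered:", rec_rep.n_recovered, "of", rec_rep.examined, "missing")

decisions, tally = rf.apply_eligibility_filter(cleaned)
labels, counts = rf.classify_all(cleaned, decisions)
print("status counts:", counts["by_status"])

index = rf.assign_index_dates(labels, cleaned.episodes, "first_eligibility")
cohorts = rf.build_cross_sectional_cohorts(labels, cleaned.episodes, index)
print(cohorts["cohort"].value_counts().to_dict())
```

Output:

```
violations: 14 repairs: 6
by family: {'attribute_domain': 4, 'relational_integrity': 4, 'historical_data': 2,
            'state_dependent': 2, 'attribute_dependency': 2}
dropped (start without end): 5
start dates recovered: 10 of 234 missing
status counts: {'enrolled': 440, 'opt_out': 337, 'not_approached': 223}
{'opt_out_6m': 281, 'completed_enrollment_6m': 266, 'not_approached_6m': 185,
 'incomplete_enrollment_6m': 121}
```

The 12 injected violations (2 per error kind) are all among the 14
flagged — duplicate keys are reported on both colliding rows — and the six
value-changing repairs (blanked out-of-domain items, normalised free text,
recomputed totals) are each tied to a ledger entry. The ten episodes
planted as recoverable get their start dates back from the contact log,
and the derived status counts match the planted 44/33/22 mixture exactly.

A `regforge` CLI mirrors the library:
`regforge synth generate`, `regforge qc run`, `regforge clean run`,
`regforge cohort classify`, `regforge windows build`, `regforge report flow`.

## Layout

- `src/regforge/model.py` — table schemas, delimited-text I/O, linkage,
  contact attribution
- `src/regforge/dq.py` — five-family quality rule engine
- `src/regforge/missing.py` — complete-case drop, start-date recovery,
  episode metrics
- `src/regforge/cohorts.py` — eligibility filter, status classification,
  PHQ-9 banding
- `src/regforge/windows.py` — index dates, window cohorts, record slices
- `src/regforge/synth.py` — synthetic registry generator + error injection
- `src/regforge/report.py` — subgroup summaries, DOT flow diagrams
- `docs/methods.md` — modelling assumptions and design decisions
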
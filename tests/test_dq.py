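"""Five-family data-quality rules: detection, repair, bookkeeping, idempotence."""

from __future__ import annotations

import pandas as pd
import pytest

from regforge import dq, synth
from tests.conftest import make_bundle, phq9


def _violations_for(report: dq.QualityReport, rule_id: str):
    return [v for v in report.violations if v.rule_id == rule_id]


class TestAttributeDomain:
    def test_phq9_item_above_domain_flagged_and_blanked(self, simple_bundle):
        simple_bundle.questionnaires.at[0, "item_1"] = 4
        report, cleaned = dq.run_quality_assessment(simple_bundle)
        hits = _violations_for(report, "phq9-item-domain")
        assert len(hits) == 1 and hits[0].action == "set_missing"
        assert pd.isna(cleaned.questionnaires.at[0, "item_1"])

    def test_boundary_values_inside_domain_pass(self, simple_bundle):
        simple_bundle.questionnaires.at[0, "item_1"] = 0
        simple_bundle.questionnaires.at[0, "item_2"] = 3
        simple_bundle.questionnaires.at[0, "total"] = int(
            simple_bundle.questionnaires.loc[0, [f"item_{i}" for i in range(1, 10)]].sum()
        )
        report, _ = dq.run_quality_assessment(simple_bundle)
        assert not _violations_for(report, "phq9-item-domain")

    def test_free_text_employment_normalised(self, simple_bundle):
        simple_bundle.demographics.at[0, "employment_status"] = "I am looking for a job"
        report, cleaned = dq.run_quality_assessment(simple_bundle)
        hits = _violations_for(report, "employment-normalize")
        assert len(hits) == 1 and hits[0].action == "normalized"
        assert cleaned.demographics.at[0, "employment_status"] == "no"

    def test_unknown_free_text_set_missing(self, simple_bundle):
        simple_bundle.demographics.at[0, "employment_status"] = "it depends"
        report, cleaned = dq.run_quality_assessment(simple_bundle)
        hits = _violations_for(report, "employment-normalize")
        assert len(hits) == 1 and hits[0].action == "set_missing"
        assert pd.isna(cleaned.demographics.at[0, "employment_status"])


class TestRelationalIntegrity:
    def test_duplicate_composite_key_flagged(self):
        bundle = make_bundle(
            episodes=[
                {"episode_id": "E1", "patient_id": "P1",
                 "eligibility_date": "2010-01-01", "start_date": "2010-01-05",
                 "end_date": "2010-03-01"},
                {"episode_id": "E2", "patient_id": "P1",
                 "eligibility_date": "2010-01-01", "start_date": "2010-01-05",
                 "end_date": "2010-04-01"},
            ]
        )
        report, _ = dq.run_quality_assessment(bundle)
        hits = _violations_for(report, "episode-key-unique")
        assert {v.row_key for v in hits} == {"E1", "E2"}
        assert all("uniqueness" in v.dimensions for v in hits)

    def test_unknown_patient_id_is_consistency_violation(self, simple_bundle):
        simple_bundle.contacts.loc[len(simple_bundle.contacts)] = {
            "patient_id": "P404",
            "contact_date": pd.Timestamp("2010-02-02"),
            "time_spent": 5,
        }
        report, _ = dq.run_quality_assessment(simple_bundle)
        hits = _violations_for(report, "child-rows-resolve")
        assert len(hits) == 1 and hits[0].dimensions == ("consistency",)

    def test_clean_fixture_has_zero_violations(self, simple_bundle):
        report, _ = dq.run_quality_assessment(simple_bundle)
        assert report.n_violations == 0


class TestHistoricalRules:
    def test_birth_after_event_flagged(self, simple_bundle):
        simple_bundle.demographics.at[0, "birth_date"] = pd.Timestamp("2015-01-01")
        report, _ = dq.run_quality_assessment(simple_bundle)
        assert len(_violations_for(report, "birth-before-events")) == 1

    def test_end_before_start_flagged(self):
        bundle = make_bundle(
            episodes=[{"episode_id": "E1", "patient_id": "P1",
                       "eligibility_date": "2010-01-01", "start_date": "2010-06-01",
                       "end_date": "2010-05-01"}]
        )
        report, _ = dq.run_quality_assessment(bundle)
        assert len(_violations_for(report, "episode-date-order")) == 1

    def test_same_day_start_and_end_is_legal(self):
        """Zero activation-time is a legal minimum, not an inversion."""
        bundle = make_bundle(
            episodes=[{"episode_id": "E1", "patient_id": "P1",
                       "eligibility_date": "2010-01-01", "start_date": "2010-01-01",
                       "end_date": "2010-01-01"}]
        )
        report, _ = dq.run_quality_assessment(bundle)
        assert not _violations_for(report, "episode-date-order")

    def test_recorded_enrolled_without_contact_flagged(self):
        bundle = make_bundle(
            episodes=[{"episode_id": "E1", "patient_id": "P1",
                       "eligibility_date": "2010-01-01", "start_date": "2010-01-05",
                       "end_date": "2010-03-01", "recorded_status": "enrolled"}]
        )
        report, _ = dq.run_quality_assessment(bundle)
        hits = _violations_for(report, "enrolled-has-contact")
        assert len(hits) == 1 and hits[0].dimensions == ("completeness",)


class TestStateDependent:
    def test_end_without_eligibility_labels_missing(self):
        bundle = make_bundle(
            episodes=[{"episode_id": "E1", "patient_id": "P1",
                       "eligibility_date": None, "start_date": None,
                       "end_date": "2010-03-01"}]
        )
        report, _ = dq.run_quality_assessment(bundle)
        hits = _violations_for(report, "end-requires-eligibility")
        assert len(hits) == 1 and hits[0].column == "eligibility_date"

    def test_questionnaire_on_enrollment_date_passes(self):
        bundle = make_bundle(
            episodes=[{"episode_id": "E1", "patient_id": "P1",
                       "eligibility_date": "2010-01-01", "start_date": "2010-01-10",
                       "end_date": "2010-06-01"}],
            questionnaires=[phq9("P1", "2010-01-10", 14)],
        )
        report, _ = dq.run_quality_assessment(bundle)
        assert not _violations_for(report, "questionnaire-before-start")

    def test_questionnaire_after_enrollment_flagged(self):
        bundle = make_bundle(
            episodes=[{"episode_id": "E1", "patient_id": "P1",
                       "eligibility_date": "2010-01-01", "start_date": "2010-01-10",
                       "end_date": "2010-06-01"}],
            questionnaires=[
                {"patient_id": "P1", "instrument": "GAD7", "total": 9,
                 "recording_date": "2010-01-20"},
            ],
        )
        report, _ = dq.run_quality_assessment(bundle)
        hits = _violations_for(report, "questionnaire-before-start")
        assert len(hits) == 1 and "10 day" in hits[0].message


class TestAttributeDependency:
    @pytest.mark.parametrize(
        "items, total, expect_violation, repaired_total",
        [
            ([3] * 9, 27, False, 27),
            ([1, 2, 1, 2, 1, 2, 1, 2, 1], 15, True, 13),
            ([0] * 9, 0, False, 0),
        ],
    )
    def test_total_must_equal_item_sum(self, items, total, expect_violation, repaired_total):
        bundle = make_bundle(
            episodes=[{"episode_id": "E1", "patient_id": "P1",
                       "eligibility_date": "2010-01-01", "start_date": None,
                       "end_date": "2010-06-01"}],
            questionnaires=[phq9("P1", "2010-01-01", total, items=items)],
        )
        report, cleaned = dq.run_quality_assessment(bundle)
        hits = _violations_for(report, "phq9-total-equals-items")
        assert bool(hits) is expect_violation
        assert int(cleaned.questionnaires.at[0, "total"]) == repaired_total


class TestOrchestration:
    def test_one_injection_per_kind_yields_one_flag_each(self):
        bundle, _ = synth.generate_registry(
            synth.GeneratorConfig(n_patients=100), seed=12
        )
        corrupted, ledger = synth.inject_errors(bundle, synth.ErrorConfig.uniform(1), 12)
        assert len(ledger) == len(synth.ERROR_KINDS)
        report, _ = dq.run_quality_assessment(corrupted)
        matched, misses = synth.ledger_recall(report.violations, ledger)
        assert matched == len(ledger), misses
        families = {e["family"] for e in ledger}
        assert families == set(dq.FAMILIES)

    def test_dimension_totals_are_exact_rule_sums(self):
        bundle, _ = synth.generate_registry(synth.GeneratorConfig(n_patients=60), seed=4)
        corrupted, _ = synth.inject_errors(bundle, synth.ErrorConfig.uniform(2), 4)
        report, _ = dq.run_quality_assessment(corrupted)
        counts = report.rule_counts
        for dim, total in report.dimension_totals.items():
            expected = sum(
                counts.get(rid, 0)
                for rid, dims in report.rule_dimensions.items()
                if dim in dims
            )
            assert total == expected

    def test_second_run_on_cleaned_output_repairs_nothing(self):
        bundle, _ = synth.generate_registry(synth.GeneratorConfig(n_patients=80), seed=9)
        corrupted, _ = synth.inject_errors(bundle, synth.ErrorConfig.uniform(3), 9)
        report1, cleaned = dq.run_quality_assessment(corrupted)
        assert report1.n_repairs > 0
        report2, _ = dq.run_quality_assessment(cleaned)
        assert report2.n_repairs == 0

    def test_rule_with_unknown_column_is_configuration_error(self, simple_bundle):
        bad = dq.QualityRule(
            "broken", "attribute_domain", "numeric_domain", ("validity",),
            "questionnaires", ("item_99",), {"lo": 0, "hi": 3},
        )
        with pytest.raises(dq.ConfigurationError, match="item_99"):
            dq.run_quality_assessment(simple_bundle, [bad])

    def test_ruleset_yaml_round_trip(self, tmp_path):
        rules = dq.default_ruleset()
        dq.dump_ruleset(rules, tmp_path / "rules.yaml")
        assert dq.load_ruleset(tmp_path / "rules.yaml") == rules
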
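"""Declarative data-quality rule engine for registry bundles.

The engine implements a five-family taxonomy of record-level quality rules,
the kind used to audit EHR-derived registries:

* ``attribute_domain`` — per-column domain constraints (PHQ-9 items in 0–3)
  and free-text categorical normalisation (employment status to yes/no).
* ``relational_integrity`` — uniqueness of the composite episode key and of
  the patient id, plus orphan child rows.
* ``historical_data`` — temporal ordering (birth before all events, episode
  dates in order) and the requirement that a recorded-enrolled episode has a
  contact date.
* ``state_dependent`` — events whose presence implies other events: an end
  date implies an eligibility date; an intake questionnaire must be recorded
  on or before the episode start date.
* ``attribute_dependency`` — aggregates must agree with their components:
  the PHQ-9 total equals the sum of its nine items.

Each check emits :class:`Violation` entries; configured repairs (normalise,
set-missing, recompute) are applied in a fixed family order (domain rules
first, so downstream rules see normalised values) and are each traceable to
exactly one violation.  Re-running the assessment on its own cleaned output
performs zero repairs.

Timeliness is deliberately not assessed; the taxonomy here covers accuracy,
completeness, consistency, validity and uniqueness only.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import model
from .model import RegistryBundle, PHQ9_ITEM_COLUMNS

logger = logging.getLogger(__name__)

FAMILIES = (
    "attribute_domain",
    "relational_integrity",
    "historical_data",
    "state_dependent",
    "attribute_dependency",
)

#: Quality dimensions each rule family may address.
FAMILY_DIMENSIONS: dict[str, frozenset[str]] = {
    "attribute_domain": frozenset({"accuracy", "consistency", "validity", "completeness"}),
    "relational_integrity": frozenset({"consistency", "uniqueness", "completeness"}),
    "historical_data": frozenset({"accuracy", "consistency", "validity", "completeness"}),
    "state_dependent": frozenset({"completeness", "consistency", "uniqueness", "accuracy"}),
    "attribute_dependency": frozenset({"accuracy"}),
}

DIMENSIONS = ("accuracy", "completeness", "consistency", "validity", "uniqueness")


class ConfigurationError(ValueError):
    """A ruleset refers to a missing column/table or is otherwise invalid."""


@dataclass(frozen=True)
class QualityRule:
    """One declarative quality rule.

    ``kind`` selects the built-in predicate; ``params`` carries its
    configuration (domain bounds, normalisation map, repair policy).
    """

    rule_id: str
    family: str
    kind: str
    dimensions: tuple[str, ...]
    table: str
    columns: tuple[str, ...] = ()
    params: dict = field(default_factory=dict)
    repair: str | None = None


@dataclass(frozen=True)
class Violation:
    """One data-quality finding, optionally tied to a repair action."""

    rule_id: str
    family: str
    dimensions: tuple[str, ...]
    table: str
    row_key: str
    column: str | None
    observed: object
    action: str  # flagged | normalized | set_missing | recomputed
    message: str


#: Repair-type actions (as opposed to pure flags); idempotence is asserted on
#: these: a second assessment of cleaned output performs zero of them.
REPAIR_ACTIONS = frozenset({"normalized", "set_missing", "recomputed"})

#: Free-text employment normalisation dictionary.  Ships with the two
#: canonical clinic phrasings and is user-extensible via the ruleset file;
#: unknown free text is set to missing with a flag.
DEFAULT_EMPLOYMENT_MAP: dict[str, str] = {
    "yes": "yes",
    "no": "no",
    "i am employed": "yes",
    "i am looking for a job": "no",
}


def default_ruleset() -> list[QualityRule]:
    """The shipped ruleset covering all five families."""
    return [
        QualityRule(
            "phq9-item-domain",
            "attribute_domain",
            "numeric_domain",
            ("validity",),
            "questionnaires",
            PHQ9_ITEM_COLUMNS,
            {"lo": 0, "hi": 3, "instrument": "PHQ9"},
            repair="set_missing",
        ),
        QualityRule(
            "phq9-total-domain",
            "attribute_domain",
            "numeric_domain",
            ("validity",),
            "questionnaires",
            ("total",),
            {"lo": 0, "hi": 27, "instrument": "PHQ9"},
            repair=None,
        ),
        QualityRule(
            "employment-normalize",
            "attribute_domain",
            "categorical_normalize",
            ("consistency",),
            "demographics",
            ("employment_status",),
            {"mapping": dict(DEFAULT_EMPLOYMENT_MAP)},
            repair="normalize",
        ),
        QualityRule(
            "episode-key-unique",
            "relational_integrity",
            "unique_key",
            ("uniqueness",),
            "episodes",
            ("patient_id", "eligibility_date", "start_date"),
        ),
        QualityRule(
            "patient-id-unique",
            "relational_integrity",
            "unique_key",
            ("uniqueness",),
            "demographics",
            ("patient_id",),
        ),
        QualityRule(
            "child-rows-resolve",
            "relational_integrity",
            "orphan",
            ("consistency",),
            "episodes",  # applies to all child tables; table names the anchor
        ),
        QualityRule(
            "birth-before-events",
            "historical_data",
            "birth_before_events",
            ("accuracy",),
            "demographics",
            ("birth_date",),
        ),
        QualityRule(
            "episode-date-order",
            "historical_data",
            "date_order",
            ("accuracy",),
            "episodes",
            ("eligibility_date", "start_date", "end_date"),
        ),
        QualityRule(
            "enrolled-has-contact",
            "historical_data",
            "enrolled_has_contact",
            ("completeness",),
            "episodes",
        ),
        QualityRule(
            "end-requires-eligibility",
            "state_dependent",
            "end_requires_eligibility",
            ("completeness",),
            "episodes",
            ("eligibility_date",),
        ),
        QualityRule(
            "questionnaire-before-start",
            "state_dependent",
            "questionnaire_before_start",
            ("consistency",),
            "questionnaires",
            ("recording_date",),
        ),
        QualityRule(
            "phq9-total-equals-items",
            "attribute_dependency",
            "total_equals_sum",
            ("accuracy",),
            "questionnaires",
            ("total",) + PHQ9_ITEM_COLUMNS,
            repair="recompute",
        ),
    ]


def validate_ruleset(rules: Sequence[QualityRule], bundle: RegistryBundle) -> None:
    for r in rules:
        if r.family not in FAMILIES:
            raise ConfigurationError(f"{r.rule_id}: unknown family {r.family!r}")
        bad = set(r.dimensions) - FAMILY_DIMENSIONS[r.family]
        if bad:
            raise ConfigurationError(
                f"{r.rule_id}: dimension(s) {sorted(bad)} not applicable to {r.family}"
            )
        if r.table not in model.TABLES:
            raise ConfigurationError(f"{r.rule_id}: unknown table {r.table!r}")
        cols = bundle.table(r.table).columns
        for c in r.columns:
            if c not in cols:
                raise ConfigurationError(f"{r.rule_id}: column {c!r} absent from {r.table}")


def load_ruleset(path: Path | str) -> list[QualityRule]:
    """Load a ruleset from YAML (list of rule mappings)."""
    raw = yaml.safe_load(Path(path).read_text())
    rules = []
    for entry in raw:
        rules.append(
            QualityRule(
                rule_id=entry["rule_id"],
                family=entry["family"],
                kind=entry["kind"],
                dimensions=tuple(entry.get("dimensions", ())),
                table=entry["table"],
                columns=tuple(entry.get("columns", ())),
                params=dict(entry.get("params", {})),
                repair=entry.get("repair"),
            )
        )
    return rules


def dump_ruleset(rules: Sequence[QualityRule], path: Path | str) -> None:
    Path(path).write_text(
        yaml.safe_dump([asdict(r) for r in rules], sort_keys=False)
    )


# ---------------------------------------------------------------------------
# Row keys
# ---------------------------------------------------------------------------

def _row_key(table: str, df: pd.DataFrame, idx) -> str:
    row = df.loc[idx]
    if table == "episodes":
        return str(row["episode_id"])
    if table == "demographics":
        return str(row["patient_id"])
    return f"{table}:{idx}"  # positional key for contact/questionnaire rows


# ---------------------------------------------------------------------------
# Family checks
# ---------------------------------------------------------------------------

def check_attribute_domain(
    bundle: RegistryBundle, rules: Sequence[QualityRule]
) -> tuple[list[Violation], RegistryBundle]:
    """Domain constraints + free-text normalisation.

    Out-of-domain numeric values are flagged and, with ``repair=set_missing``,
    blanked; free-text categoricals are mapped through the normalisation
    dictionary (unknown text becomes missing).  Returns the normalised bundle.
    """
    out = bundle.copy()
    violations: list[Violation] = []
    for rule in rules:
        df = out.table(rule.table)
        if rule.kind == "numeric_domain":
            lo, hi = rule.params["lo"], rule.params["hi"]
            instrument = rule.params.get("instrument")
            scope = df.index
            if instrument is not None and "instrument" in df.columns:
                scope = df.index[df["instrument"] == instrument]
            for col in rule.columns:
                vals = df.loc[scope, col]
                bad = scope[vals.notna() & ((vals < lo) | (vals > hi))]
                for idx in bad:
                    action = "set_missing" if rule.repair == "set_missing" else "flagged"
                    violations.append(
                        Violation(
                            rule.rule_id,
                            rule.family,
                            rule.dimensions,
                            rule.table,
                            _row_key(rule.table, df, idx),
                            col,
                            int(df.at[idx, col]),
                            action,
                            f"{col}={df.at[idx, col]} outside domain [{lo}, {hi}]",
                        )
                    )
                    if rule.repair == "set_missing":
                        df.at[idx, col] = pd.NA
        elif rule.kind == "categorical_normalize":
            mapping = {
                k.strip().lower(): v for k, v in rule.params["mapping"].items()
            }
            (col,) = rule.columns
            for idx in df.index[df[col].notna()]:
                raw = str(df.at[idx, col])
                canon = mapping.get(raw.strip().lower())
                if canon == raw:
                    continue
                if canon is not None:
                    violations.append(
                        Violation(
                            rule.rule_id,
                            rule.family,
                            rule.dimensions,
                            rule.table,
                            _row_key(rule.table, df, idx),
                            col,
                            raw,
                            "normalized",
                            f"free-text {raw!r} normalized to {canon!r}",
                        )
                    )
                    df.at[idx, col] = canon
                else:
                    violations.append(
                        Violation(
                            rule.rule_id,
                            rule.family,
                            rule.dimensions,
                            rule.table,
                            _row_key(rule.table, df, idx),
                            col,
                            raw,
                            "set_missing",
                            f"unmapped free-text {raw!r} set to missing",
                        )
                    )
                    df.at[idx, col] = pd.NA
        else:  # pragma: no cover - guarded by validate_ruleset
            raise ConfigurationError(f"unknown attribute_domain kind {rule.kind!r}")
    return violations, out


def check_relational_integrity(
    bundle: RegistryBundle, rules: Sequence[QualityRule]
) -> list[Violation]:
    """Duplicate keys and orphan child rows."""
    violations: list[Violation] = []
    linked = model.link_records(bundle)
    for rule in rules:
        if rule.kind == "unique_key":
            df = bundle.table(rule.table)
            if rule.table == "episodes":
                keys = linked.linkage["composite_key"]
            else:
                keys = df[list(rule.columns)].astype(str).agg("|".join, axis=1)
            dup_mask = keys.duplicated(keep=False)
            for idx in df.index[dup_mask]:
                violations.append(
                    Violation(
                        rule.rule_id,
                        rule.family,
                        rule.dimensions,
                        rule.table,
                        _row_key(rule.table, df, idx),
                        None,
                        keys.loc[idx],
                        "flagged",
                        f"duplicate key {keys.loc[idx]!r}",
                    )
                )
        elif rule.kind == "orphan":
            for t, orphans in linked.orphans.items():
                df = bundle.table(t)
                for idx in orphans.index:
                    violations.append(
                        Violation(
                            rule.rule_id,
                            rule.family,
                            rule.dimensions,
                            t,
                            _row_key(t, df, idx),
                            "patient_id",
                            orphans.at[idx, "patient_id"],
                            "flagged",
                            "patient_id does not resolve to a demographics row",
                        )
                    )
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown relational kind {rule.kind!r}")
    return violations


def check_historical_rules(
    bundle: RegistryBundle, rules: Sequence[QualityRule]
) -> list[Violation]:
    """Temporal-order rules over dates."""
    violations: list[Violation] = []
    episodes = bundle.episodes
    for rule in rules:
        if rule.kind == "birth_before_events":
            demo = bundle.demographics
            events = []
            for t, col in (
                ("episodes", "eligibility_date"),
                ("episodes", "start_date"),
                ("episodes", "end_date"),
                ("contacts", "contact_date"),
                ("questionnaires", "recording_date"),
            ):
                df = bundle.table(t)
                events.append(df[["patient_id", col]].rename(columns={col: "date"}))
            ev = pd.concat(events, ignore_index=True).dropna()
            first = ev.groupby("patient_id")["date"].min()
            for idx in demo.index:
                pid, born = demo.at[idx, "patient_id"], demo.at[idx, "birth_date"]
                if pd.isna(born) or pid not in first.index:
                    continue
                if first[pid] < born:
                    violations.append(
                        Violation(
                            rule.rule_id,
                            rule.family,
                            rule.dimensions,
                            "demographics",
                            str(pid),
                            "birth_date",
                            str(born.date()),
                            "flagged",
                            f"birth date {born.date()} after first event {first[pid].date()}",
                        )
                    )
        elif rule.kind == "date_order":
            for idx in episodes.index:
                e = episodes.loc[idx]
                elig, start, end = e["eligibility_date"], e["start_date"], e["end_date"]
                problems = []
                if pd.notna(start) and pd.notna(end) and end < start:
                    problems.append("end_date before start_date")
                if pd.notna(elig) and pd.notna(start) and start < elig:
                    problems.append("start_date before eligibility_date")
                if pd.notna(elig) and pd.notna(end) and pd.isna(start) and end < elig:
                    problems.append("end_date before eligibility_date")
                if problems:
                    violations.append(
                        Violation(
                            rule.rule_id,
                            rule.family,
                            rule.dimensions,
                            "episodes",
                            str(e["episode_id"]),
                            None,
                            f"elig={elig} start={start} end={end}",
                            "flagged",
                            "; ".join(problems),
                        )
                    )
        elif rule.kind == "enrolled_has_contact":
            # Scoped to episodes whose status was *recorded* as enrolled; a
            # start-date episode with no contacts and no recorded status is a
            # cohort-classification case (opt-out), not a data error.
            rec = episodes["recorded_status"] == "enrolled"
            if rec.any():
                attributed = model.attribute_contacts(bundle)
                with_contact = set(attributed.dropna())
                for idx in episodes.index[rec]:
                    eid = episodes.at[idx, "episode_id"]
                    if eid not in with_contact:
                        violations.append(
                            Violation(
                                rule.rule_id,
                                rule.family,
                                rule.dimensions,
                                "episodes",
                                str(eid),
                                "contact_date",
                                None,
                                "flagged",
                                "recorded-enrolled episode has no contact date; "
                                "contact date labeled missing",
                            )
                        )
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown historical kind {rule.kind!r}")
    return violations


def check_state_dependent(
    bundle: RegistryBundle, rules: Sequence[QualityRule]
) -> list[Violation]:
    """Presence/ordering implications between linked events."""
    violations: list[Violation] = []
    episodes = bundle.episodes
    for rule in rules:
        if rule.kind == "end_requires_eligibility":
            mask = episodes["end_date"].notna() & episodes["eligibility_date"].isna()
            for idx in episodes.index[mask]:
                violations.append(
                    Violation(
                        rule.rule_id,
                        rule.family,
                        rule.dimensions,
                        "episodes",
                        str(episodes.at[idx, "episode_id"]),
                        "eligibility_date",
                        None,
                        "flagged",
                        "episode has an end date but eligibility date is labeled missing",
                    )
                )
        elif rule.kind == "questionnaire_before_start":
            quest = bundle.questionnaires
            if quest.empty:
                continue
            attributed = model.attribute_questionnaires(bundle)
            starts = episodes.set_index("episode_id")["start_date"]
            for idx in quest.index:
                eid = attributed.loc[idx]
                if pd.isna(eid):
                    continue
                start = starts.get(eid)
                rec = quest.at[idx, "recording_date"]
                if pd.notna(start) and pd.notna(rec) and rec > start:
                    violations.append(
                        Violation(
                            rule.rule_id,
                            rule.family,
                            rule.dimensions,
                            "questionnaires",
                            _row_key("questionnaires", quest, idx),
                            "recording_date",
                            str(rec.date()),
                            "flagged",
                            f"{quest.at[idx, 'instrument']} recorded {int((rec - start).days)}"
                            f" day(s) after episode start",
                        )
                    )
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown state_dependent kind {rule.kind!r}")
    return violations


def check_attribute_dependency(
    bundle: RegistryBundle, rules: Sequence[QualityRule]
) -> tuple[list[Violation], RegistryBundle]:
    """Aggregate-consistency rules (PHQ-9 total vs item sum) with repair."""
    out = bundle.copy()
    violations: list[Violation] = []
    for rule in rules:
        if rule.kind != "total_equals_sum":  # pragma: no cover
            raise ConfigurationError(f"unknown dependency kind {rule.kind!r}")
        df = out.table(rule.table)
        scope = df.index[df["instrument"] == "PHQ9"] if "instrument" in df.columns else df.index
        items = df.loc[scope, list(PHQ9_ITEM_COLUMNS)]
        complete = items.notna().all(axis=1)
        sums = items.sum(axis=1)
        for idx in scope[complete & df.loc[scope, "total"].notna()]:
            total, s = df.at[idx, "total"], int(sums.loc[idx])
            if int(total) != s:
                repair = rule.repair or "recompute"
                action = "recomputed" if repair == "recompute" else "set_missing"
                violations.append(
                    Violation(
                        rule.rule_id,
                        rule.family,
                        rule.dimensions,
                        rule.table,
                        _row_key(rule.table, df, idx),
                        "total",
                        int(total),
                        action,
                        f"recorded total {int(total)} != item sum {s}",
                    )
                )
                df.at[idx, "total"] = s if repair == "recompute" else pd.NA
    return violations, out


# ---------------------------------------------------------------------------
# Report and orchestration
# ---------------------------------------------------------------------------

@dataclass
class QualityReport:
    """Violation ledger with per-rule, per-dimension and repair bookkeeping."""

    violations: list[Violation]
    rule_dimensions: dict[str, tuple[str, ...]]
    table_completeness: dict[str, float]

    @property
    def rule_counts(self) -> dict[str, int]:
        return dict(Counter(v.rule_id for v in self.violations))

    @property
    def family_counts(self) -> dict[str, int]:
        return dict(Counter(v.family for v in self.violations))

    @property
    def dimension_totals(self) -> dict[str, int]:
        counts = self.rule_counts
        totals = {d: 0 for d in DIMENSIONS}
        for rule_id, dims in self.rule_dimensions.items():
            for d in dims:
                totals[d] += counts.get(rule_id, 0)
        return totals

    @property
    def n_violations(self) -> int:
        return len(self.violations)

    @property
    def n_repairs(self) -> int:
        return sum(1 for v in self.violations if v.action in REPAIR_ACTIONS)

    def to_dict(self) -> dict:
        return {
            "n_violations": self.n_violations,
            "n_repairs": self.n_repairs,
            "rule_counts": self.rule_counts,
            "family_counts": self.family_counts,
            "dimension_totals": self.dimension_totals,
            "table_completeness": self.table_completeness,
        }

    def to_json(self, path: Path | str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_frame(self) -> pd.DataFrame:
        """Violation ledger as a flat table (exportable as delimited text)."""
        return pd.DataFrame(
            [
                {
                    "rule_id": v.rule_id,
                    "family": v.family,
                    "table": v.table,
                    "row_key": v.row_key,
                    "column": v.column,
                    "observed": v.observed,
                    "action": v.action,
                    "message": v.message,
                }
                for v in self.violations
            ],
            columns=[
                "rule_id",
                "family",
                "table",
                "row_key",
                "column",
                "observed",
                "action",
                "message",
            ],
        )

    def summary_text(self) -> str:
        lines = [f"violations: {self.n_violations} (repairs: {self.n_repairs})"]
        for fam in FAMILIES:
            lines.append(f"  {fam}: {self.family_counts.get(fam, 0)}")
        lines.append("dimension totals:")
        for d, n in self.dimension_totals.items():
            lines.append(f"  {d}: {n}")
        return "\n".join(lines)


def _completeness(bundle: RegistryBundle) -> dict[str, float]:
    rates = {}
    for t in model.TABLES:
        df = bundle.table(t)[list(model.REQUIRED_COLUMNS[t])]
        cells = df.size
        rates[t] = 1.0 if cells == 0 else float(df.notna().sum().sum() / cells)
    return rates


def run_quality_assessment(
    bundle: RegistryBundle,
    ruleset: Sequence[QualityRule] | None = None,
) -> tuple[QualityReport, RegistryBundle]:
    """Execute all five rule families in fixed order and apply repairs.

    Order: domain → relational → historical → state-dependent → dependency,
    so that dependency rules see normalised values (e.g. an out-of-domain
    PHQ-9 item is blanked before the total/sum comparison, which then skips
    the incomplete row instead of double-flagging it).
    """
    rules = list(default_ruleset() if ruleset is None else ruleset)
    validate_ruleset(rules, bundle)
    by_family: dict[str, list[QualityRule]] = {f: [] for f in FAMILIES}
    for r in rules:
        by_family[r.family].append(r)

    violations: list[Violation] = []
    v, bundle = check_attribute_domain(bundle, by_family["attribute_domain"])
    violations += v
    violations += check_relational_integrity(bundle, by_family["relational_integrity"])
    violations += check_historical_rules(bundle, by_family["historical_data"])
    violations += check_state_dependent(bundle, by_family["state_dependent"])
    v, bundle = check_attribute_dependency(bundle, by_family["attribute_dependency"])
    violations += v

    report = QualityReport(
        violations=violations,
        rule_dimensions={r.rule_id: r.dimensions for r in rules},
        table_completeness=_completeness(bundle),
    )
    logger.info("quality assessment: %s", report.to_dict())
    return report, bundle
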
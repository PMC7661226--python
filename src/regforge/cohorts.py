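"""Episode status classification, eligibility filtering and PHQ-9 banding.

Every eligible patient instance is assigned exactly one of three statuses:

* ``enrolled`` — the patient received the collaborative-care intervention;
* ``opt_out`` — the patient was offered the intervention (start date
  present) but the contact log shows no engagement (zero contact frequency
  or zero total time spent);
* ``not_approached`` — the patient met eligibility criteria but was never
  offered the intervention (start date missing after recovery).

A status recorded by the clinic takes precedence over any derived status.
Derivation otherwise follows two contact-log algorithms: for instances with
a start date, positive contact frequency *and* positive total time imply
enrollment (algorithm A); for instances whose start date was recovered from
the contact log, the instance is enrolled (algorithm B); an instance whose
start date is still missing was never approached.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from . import missing, model
from .model import RegistryBundle, START_PROVENANCE_COLUMN

logger = logging.getLogger(__name__)

STATUSES = ("enrolled", "opt_out", "not_approached")

PROVENANCES = ("recorded", "derived_A", "derived_B_recovered", "derived_B_unapproached")

EXCLUSION_REASONS = (
    "no_consent",
    "age_below_18",
    "bipolar_history",
    "phq_below_10",
    "fewer_than_two_phq9",
    "no_depression_diagnosis",
)

#: PHQ-9 severity bands as reported in registry subgroup summaries.
PHQ9_BANDS = ("<=5", ">5, <10", ">=10, <15", ">=15, <20", ">=20", "missing")


class DomainError(ValueError):
    pass


@dataclass(frozen=True)
class StatusLabel:
    episode_id: str
    status: str
    provenance: str


@dataclass(frozen=True)
class EligibilityCriteria:
    """Study inclusion/exclusion configuration.

    Defaults mirror a depression-registry cross-sectional design: adults
    (>=18 at the eligibility date) with a depression diagnosis, no bipolar
    history, research consent, and a baseline PHQ-9 >= 10.  Enrolled
    (approached) instances below the PHQ-9 threshold are retained under the
    provider-discretion override when ``subthreshold_override`` is on.
    The >=2-PHQ-9 requirement belongs to the cross-sectional pathway only
    and is off by default.
    """

    min_age: int = 18
    require_consent: bool = True
    exclude_bipolar: bool = True
    min_phq9: int = 10
    require_depression_diagnosis: bool = True
    require_two_phq9: bool = False
    subthreshold_override: bool = True


@dataclass(frozen=True)
class EligibilityDecision:
    episode_id: str
    eligible: bool
    exclusion_reasons: tuple[str, ...]
    subthreshold_override: bool = False


def band_phq9(score) -> str:
    """Map a PHQ-9 total (0-27, or missing) to its severity band."""
    if score is None or pd.isna(score):
        return "missing"
    score = int(score)
    if not 0 <= score <= 27:
        raise DomainError(f"PHQ-9 total {score} outside 0-27")
    if score <= 5:
        return "<=5"
    if score < 10:
        return ">5, <10"
    if score < 15:
        return ">=10, <15"
    if score < 20:
        return ">=15, <20"
    return ">=20"


def _truthy(v) -> bool:
    return (not pd.isna(v)) and bool(v)


def _age_at(date: pd.Timestamp, birth: pd.Timestamp) -> int:
    years = date.year - birth.year
    if (date.month, date.day) < (birth.month, birth.day):
        years -= 1
    return years


def baseline_phq9(bundle: RegistryBundle, anchor: str = "eligibility_date") -> pd.Series:
    """Latest PHQ-9 total recorded on or before each episode's anchor date.

    Returns an Int64 Series indexed like ``bundle.episodes`` (missing when
    the patient has no PHQ-9 on or before the anchor).
    """
    episodes = bundle.episodes
    quest = bundle.questionnaires
    phq = quest[(quest["instrument"] == "PHQ9") & quest["recording_date"].notna()]
    out = pd.Series(pd.NA, index=episodes.index, dtype="Int64")
    if phq.empty:
        return out
    epi = episodes[["patient_id", anchor]].reset_index(names="_row")
    m = epi.merge(
        phq[["patient_id", "recording_date", "total"]], on="patient_id", how="inner"
    )
    m = m[m[anchor].notna() & (m["recording_date"] <= m[anchor])]
    if m.empty:
        return out
    m = m.sort_values(["_row", "recording_date"])
    best = m.groupby("_row").tail(1).set_index("_row")["total"]
    out.loc[best.index] = best.to_numpy()
    return out


def apply_eligibility_filter(
    bundle: RegistryBundle,
    criteria: EligibilityCriteria = EligibilityCriteria(),
) -> tuple[list[EligibilityDecision], dict[str, int]]:
    """Evaluate study eligibility for every episode.

    Exclusions are evaluated in fixed order: research consent first, then
    the clinical inclusion criteria.  The returned tally counts episodes per
    exclusion reason (an episode failing consent is not further evaluated).
    """
    episodes = bundle.episodes
    demo = bundle.demographics.drop_duplicates("patient_id").set_index("patient_id")
    phq_baseline = baseline_phq9(bundle)
    phq_counts = (
        bundle.questionnaires[bundle.questionnaires["instrument"] == "PHQ9"]
        .groupby("patient_id")
        .size()
    )
    decisions: list[EligibilityDecision] = []
    tally: Counter = Counter()
    for idx in episodes.index:
        e = episodes.loc[idx]
        eid, pid = e["episode_id"], e["patient_id"]
        d = demo.loc[pid] if pid in demo.index else None
        reasons: list[str] = []
        override = False
        if criteria.require_consent and (d is None or not _truthy(d["consent"])):
            reasons.append("no_consent")
        else:
            if criteria.min_age is not None:
                born = None if d is None else d["birth_date"]
                elig = e["eligibility_date"]
                if pd.isna(born) or pd.isna(elig) or _age_at(elig, born) < criteria.min_age:
                    reasons.append("age_below_18")
            if criteria.exclude_bipolar and (d is None or _truthy(d["bipolar_history"])):
                reasons.append("bipolar_history")
            if criteria.require_depression_diagnosis and (
                d is None or not _truthy(d["depression_diagnosis"])
            ):
                reasons.append("no_depression_diagnosis")
            score = phq_baseline.loc[idx]
            if pd.isna(score) or int(score) < criteria.min_phq9:
                if criteria.subthreshold_override and pd.notna(e["start_date"]):
                    override = True  # approached despite subthreshold PHQ-9
                else:
                    reasons.append("phq_below_10")
            if criteria.require_two_phq9 and phq_counts.get(pid, 0) < 2:
                reasons.append("fewer_than_two_phq9")
        for r in reasons:
            tally[r] += 1
        decisions.append(
            EligibilityDecision(
                episode_id=eid,
                eligible=not reasons,
                exclusion_reasons=tuple(reasons),
                subthreshold_override=override,
            )
        )
    tally_out = {r: tally.get(r, 0) for r in EXCLUSION_REASONS}
    tally_out["n_episodes"] = len(decisions)
    tally_out["n_eligible"] = sum(d.eligible for d in decisions)
    tally_out["n_excluded"] = len(decisions) - tally_out["n_eligible"]
    tally_out["n_subthreshold_override"] = sum(d.subthreshold_override for d in decisions)
    logger.info("eligibility filter: %s", tally_out)
    return decisions, tally_out


def classify_episode(
    episode: model.Episode | pd.Series,
    metrics: missing.EpisodeMetrics,
    provenance: str = "recorded",
) -> StatusLabel:
    """Pure status classification of one episode.

    ``provenance`` is the start-date provenance ("recorded", "recovered" or
    "missing").  A recorded status always wins; otherwise algorithm A uses
    contact frequency and total time, algorithm B the recovery outcome.
    """
    if isinstance(episode, pd.Series):
        episode = model.Episode.from_row(episode)
    if metrics is None:
        raise ValueError(f"metrics undefined for episode {episode.episode_id}")
    if episode.recorded_status in ("enrolled", "opt_out"):
        return StatusLabel(episode.episode_id, episode.recorded_status, "recorded")
    if episode.start_date is None:
        return StatusLabel(episode.episode_id, "not_approached", "derived_B_unapproached")
    if provenance == "recovered":
        return StatusLabel(episode.episode_id, "enrolled", "derived_B_recovered")
    if metrics.contact_frequency > 0 and metrics.total_time_spent_min > 0:
        return StatusLabel(episode.episode_id, "enrolled", "derived_A")
    return StatusLabel(episode.episode_id, "opt_out", "derived_A")


def classify_all(
    bundle: RegistryBundle,
    decisions: list[EligibilityDecision] | None = None,
    metrics: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Classify every eligible episode; returns labels and partition counts.

    ``decisions`` restricts classification to eligible episodes (all
    episodes when omitted).  ``metrics`` is the frame from
    :func:`regforge.missing.compute_all_metrics` (computed when omitted).
    """
    episodes = bundle.episodes
    if metrics is None:
        metrics = missing.compute_all_metrics(bundle)
    eligible_ids = None
    if decisions is not None:
        eligible_ids = {d.episode_id for d in decisions if d.eligible}
    labels = []
    for idx in episodes.index:
        e = episodes.loc[idx]
        eid = e["episode_id"]
        if eligible_ids is not None and eid not in eligible_ids:
            continue
        if eid not in metrics.index:
            raise ValueError(
                f"episode {eid} has no metrics (missing end date?); "
                "run the complete-case drop first"
            )
        m = metrics.loc[eid]
        em = missing.EpisodeMetrics(
            episode_id=eid,
            activation_time_days=None
            if pd.isna(m["activation_time_days"])
            else int(m["activation_time_days"]),
            eligibility_time_days=None
            if pd.isna(m["eligibility_time_days"])
            else int(m["eligibility_time_days"]),
            ce_time_days=None if pd.isna(m["ce_time_days"]) else int(m["ce_time_days"]),
            contact_frequency=int(m["contact_frequency"]),
            total_time_spent_min=int(m["total_time_spent_min"]),
        )
        prov = e.get(START_PROVENANCE_COLUMN, "recorded")
        labels.append(classify_episode(e, em, provenance=prov))
    frame = pd.DataFrame(
        [(l.episode_id, l.status, l.provenance) for l in labels],
        columns=["episode_id", "status", "provenance"],
    )
    counts = {
        "total": len(frame),
        "by_status": {s: int((frame["status"] == s).sum()) for s in STATUSES},
        "by_provenance": {
            p: int((frame["provenance"] == p).sum()) for p in PROVENANCES
        },
    }
    assert sum(counts["by_status"].values()) == counts["total"]
    logger.info("classification: %s", counts)
    return frame, counts
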
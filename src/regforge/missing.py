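"""Missing-data handling and derived episode metrics.

Two procedures are applied, in order, to a loaded registry bundle:

1. **Complete-case drop** — a patient instance with a start date but no end
   date is a data-entry artefact (the registry requires an end date for
   every instance) and is removed at the *episode* level; the patient's
   other episodes survive.
2. **Start-date recovery** — for an instance with a missing start date, the
   eligibility-time (end date minus eligibility date) is computed; if it is
   positive and the contact log holds attributable contacts inside the
   episode's ``[eligibility_date, end_date]`` interval, the earliest contact
   date is taken as the start date (provenance ``recovered``) and the
   CE-time (end date minus first contact date) becomes defined.

Derived metrics per episode:

* ``activation_time_days`` (SE-time) — end minus start, defined iff a start
  date is present;
* ``eligibility_time_days`` — end minus eligibility, defined iff the start
  date is missing;
* ``ce_time_days`` — end minus first contact date, defined iff the start
  date was recovered;
* ``contact_frequency`` / ``total_time_spent_min`` — count and summed
  minutes of attributable contacts (contacts with a missing date are
  retained in the table but excluded here).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import model
from .model import RegistryBundle, START_PROVENANCE_COLUMN

logger = logging.getLogger(__name__)


class MissingEndDateError(ValueError):
    """Metrics were requested for an episode without an end date."""


@dataclass(frozen=True)
class EpisodeMetrics:
    episode_id: str
    activation_time_days: int | None
    eligibility_time_days: int | None
    ce_time_days: int | None
    contact_frequency: int
    total_time_spent_min: int


@dataclass
class RecoveryReport:
    """Outcome of one missing-data procedure.

    ``dropped`` + ``recovered`` + ``untouched`` partition the episode set
    examined by the procedure.
    """

    examined: int
    dropped: list[str] = field(default_factory=list)
    recovered: dict[str, str] = field(default_factory=dict)  # episode_id -> date
    untouched: list[str] = field(default_factory=list)
    mechanism: str | None = None  # narrative MCAR/MAR/MNAR annotation

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    @property
    def n_recovered(self) -> int:
        return len(self.recovered)

    @property
    def n_untouched(self) -> int:
        return len(self.untouched)

    def to_dict(self) -> dict:
        return {
            "examined": self.examined,
            "n_dropped": self.n_dropped,
            "n_recovered": self.n_recovered,
            "n_untouched": self.n_untouched,
            "dropped": list(self.dropped),
            "recovered": dict(self.recovered),
            "mechanism": self.mechanism,
        }

    def to_json(self, path: Path | str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def compute_episode_metrics(
    episode: model.Episode | pd.Series,
    contacts: pd.DataFrame,
    provenance: str | None = None,
) -> EpisodeMetrics:
    """Metrics for one episode given its *attributable* contacts.

    ``contacts`` must already be restricted to this episode per the
    attribution policy (closed ``[eligibility_date, end_date]`` interval);
    rows with a missing contact date are ignored here.
    """
    if isinstance(episode, pd.Series):
        episode = model.Episode.from_row(episode)
    if episode.end_date is None:
        raise MissingEndDateError(
            f"episode {episode.episode_id} has no end date; it should have been "
            "dropped by the complete-case procedure"
        )
    dated = contacts[contacts["contact_date"].notna()] if len(contacts) else contacts
    freq = int(len(dated))
    total = int(dated["time_spent"].fillna(0).sum()) if freq else 0
    activation = eligibility = ce = None
    if episode.start_date is not None:
        activation = int((episode.end_date - episode.start_date).days)
    elif episode.eligibility_date is not None:
        eligibility = int((episode.end_date - episode.eligibility_date).days)
    if provenance == "recovered" and freq:
        first = dated["contact_date"].min()
        ce = int((episode.end_date - first).days)
    return EpisodeMetrics(
        episode_id=episode.episode_id,
        activation_time_days=activation,
        eligibility_time_days=eligibility,
        ce_time_days=ce,
        contact_frequency=freq,
        total_time_spent_min=total,
    )


def compute_all_metrics(bundle: RegistryBundle) -> pd.DataFrame:
    """Vectorised metrics for every episode with an end date.

    Returns a frame indexed by ``episode_id`` with the five metric columns.
    Episodes lacking an end date are excluded (they are dropped upstream).
    """
    episodes = bundle.episodes
    attributed = model.attribute_contacts(bundle)
    contacts = bundle.contacts.assign(_episode=attributed)
    dated = contacts[contacts["_episode"].notna() & contacts["contact_date"].notna()]
    freq = dated.groupby("_episode").size()
    total = dated.groupby("_episode")["time_spent"].sum()
    first_contact = dated.groupby("_episode")["contact_date"].min()

    keep = episodes[episodes["end_date"].notna()]
    idx = keep["episode_id"]
    has_start = keep["start_date"].notna()
    activation = (keep["end_date"] - keep["start_date"]).dt.days
    eligibility = (keep["end_date"] - keep["eligibility_date"]).dt.days
    prov = (
        keep[START_PROVENANCE_COLUMN]
        if START_PROVENANCE_COLUMN in keep.columns
        else pd.Series("recorded", index=keep.index)
    )
    fc = idx.map(first_contact)
    ce = (keep["end_date"] - fc).dt.days

    out = pd.DataFrame(
        {
            "activation_time_days": activation.where(has_start).astype("Int64").to_numpy(),
            "eligibility_time_days": eligibility.where(~has_start).astype("Int64").to_numpy(),
            "ce_time_days": ce.where((prov == "recovered").to_numpy()).astype("Int64").to_numpy(),
            "contact_frequency": idx.map(freq).fillna(0).astype("int64").to_numpy(),
            "total_time_spent_min": idx.map(total).fillna(0).astype("int64").to_numpy(),
        },
        index=pd.Index(idx.to_numpy(), name="episode_id"),
    )
    return out


def drop_incomplete_episodes(
    bundle: RegistryBundle,
) -> tuple[RegistryBundle, RecoveryReport]:
    """Complete-case removal of episodes with a start date but no end date."""
    out = bundle.copy()
    episodes = out.episodes
    mask = episodes["start_date"].notna() & episodes["end_date"].isna()
    dropped = episodes.loc[mask, "episode_id"].tolist()
    out.episodes = episodes[~mask].reset_index(drop=True)
    report = RecoveryReport(
        examined=len(episodes),
        dropped=dropped,
        untouched=episodes.loc[~mask, "episode_id"].tolist(),
        mechanism="MCAR",
    )
    logger.info(
        "complete-case drop: %d of %d episodes removed", report.n_dropped, report.examined
    )
    return out, report


def recover_start_dates(
    bundle: RegistryBundle,
) -> tuple[RegistryBundle, RecoveryReport]:
    """Recover missing start dates from the contact log.

    For each episode with a missing start date and positive eligibility-time,
    the earliest attributable contact date becomes the start date.  The
    recovered date always lies within ``[eligibility_date, end_date]`` by
    construction of the attribution interval.
    """
    out = bundle.copy()
    episodes = out.episodes
    if START_PROVENANCE_COLUMN not in episodes.columns:
        episodes[START_PROVENANCE_COLUMN] = [
            "recorded" if ok else "missing" for ok in episodes["start_date"].notna()
        ]
    missing = episodes.index[episodes["start_date"].isna()]
    attributed = model.attribute_contacts(out)
    contacts = out.contacts.assign(_episode=attributed)
    dated = contacts[contacts["_episode"].notna() & contacts["contact_date"].notna()]
    first_contact = dated.groupby("_episode")["contact_date"].min()

    recovered: dict[str, str] = {}
    untouched: list[str] = []
    for idx in missing:
        e = episodes.loc[idx]
        eid = e["episode_id"]
        elig, end = e["eligibility_date"], e["end_date"]
        if pd.isna(elig) or pd.isna(end):
            untouched.append(eid)
            continue
        eligibility_time = int((end - elig).days)
        if eligibility_time <= 0:
            untouched.append(eid)
            continue
        first = first_contact.get(eid)
        if first is None or pd.isna(first):
            untouched.append(eid)
            continue
        episodes.at[idx, "start_date"] = first
        episodes.at[idx, START_PROVENANCE_COLUMN] = "recovered"
        recovered[eid] = str(pd.Timestamp(first).date())
    report = RecoveryReport(
        examined=len(missing), recovered=recovered, untouched=untouched
    )
    logger.info(
        "start-date recovery: %d of %d missing-start episodes recovered",
        report.n_recovered,
        report.examined,
    )
    return out, report


def clean_bundle(
    bundle: RegistryBundle,
) -> tuple[RegistryBundle, RecoveryReport, RecoveryReport]:
    """Convenience: complete-case drop followed by start-date recovery."""
    b, drop_report = drop_incomplete_episodes(bundle)
    b, recovery_report = recover_start_dates(b)
    return b, drop_report, recovery_report
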
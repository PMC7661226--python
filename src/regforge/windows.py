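"""Index-date strategies and cross-sectional window cohorts.

For a registry where patients can be eligible, offered and enrolled several
times, the start of follow-up (the *index date*) is ambiguous.  Three
strategies are supported:

* ``first_eligibility`` — everyone is indexed at their earliest eligibility
  date, regardless of arm; all patients share a comparable window.
* ``enrollment_linked`` — intervention (ever-enrolled) patients are indexed
  at the start date of their first enrolled episode (intent-to-treat);
  comparison patients at a configurable eligibility pick (first by default).
* ``shifted_eligibility`` — intervention patients as above; comparison
  patients at their chosen eligibility date plus the mean
  eligibility-to-enrollment lag observed in the intervention arm, rounded to
  whole days, to equalise the implicit pre-index delay.

Under ``first_eligibility`` (the special case), each patient falls into
exactly one of four cross-sectional cohorts for a fixed window (183 days by
default): ``completed_enrollment`` (an enrolled episode starts in-window and
ends before the window closes), ``incomplete_enrollment`` (starts in-window,
ends later), ``opt_out`` (an opt-out episode in-window, no qualifying
enrollment), ``not_approached`` (neither).  All windows are half-open
``[index, index + w)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .model import RegistryBundle

logger = logging.getLogger(__name__)

STRATEGIES = ("first_eligibility", "enrollment_linked", "shifted_eligibility")

COHORTS = (
    "completed_enrollment_6m",
    "opt_out_6m",
    "incomplete_enrollment_6m",
    "not_approached_6m",
)

#: Default window length: six months encoded as 183 days.
DEFAULT_WINDOW_DAYS = 183


class UndefinedLagError(ValueError):
    """Mean eligibility-to-enrollment lag requested with no enrolled episodes."""


@dataclass(frozen=True)
class IndexAssignment:
    patient_id: str
    index_date: pd.Timestamp
    strategy: str
    arm: str  # intervention | comparison


def _labelled(labels: pd.DataFrame, episodes: pd.DataFrame) -> pd.DataFrame:
    return labels.merge(episodes, on="episode_id", how="left", validate="1:1")


def mean_eligibility_to_enrollment_lag(
    labels: pd.DataFrame, episodes: pd.DataFrame
) -> float:
    """Mean (start − eligibility) in days over enrolled episodes."""
    m = _labelled(labels, episodes)
    m = m[
        (m["status"] == "enrolled")
        & m["start_date"].notna()
        & m["eligibility_date"].notna()
    ]
    if m.empty:
        raise UndefinedLagError("no enrolled episode with both dates")
    return float((m["start_date"] - m["eligibility_date"]).dt.days.mean())


def _first_enrolled_start(m: pd.DataFrame) -> pd.DataFrame:
    """Per patient, the start date of the first enrolled episode.

    First = minimum start date; ties broken by minimum eligibility date,
    then episode id.
    """
    enrolled = m[(m["status"] == "enrolled") & m["start_date"].notna()]
    enrolled = enrolled.sort_values(["start_date", "eligibility_date", "episode_id"])
    return enrolled.groupby("patient_id").head(1)[["patient_id", "start_date"]]


def assign_index_dates(
    labels: pd.DataFrame,
    episodes: pd.DataFrame,
    strategy: str = "first_eligibility",
    comparison_pick: str = "first",
    mean_lag_days: float | None = None,
) -> pd.DataFrame:
    """Assign one index date per labelled patient under ``strategy``.

    Returns a frame with columns patient_id, index_date, strategy, arm.
    Patients without a qualifying episode (no usable date) are excluded with
    a log entry.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if comparison_pick not in ("first", "last"):
        raise ValueError(f"comparison_pick must be 'first' or 'last'")
    m = _labelled(labels, episodes)
    enrolled_patients = set(m.loc[m["status"] == "enrolled", "patient_id"])
    arm = {
        pid: ("intervention" if pid in enrolled_patients else "comparison")
        for pid in m["patient_id"].unique()
    }
    elig = m[m["eligibility_date"].notna()].groupby("patient_id")["eligibility_date"]
    elig_pick = elig.min() if comparison_pick == "first" else elig.max()
    first_elig = m[m["eligibility_date"].notna()].groupby("patient_id")[
        "eligibility_date"
    ].min()

    rows = []
    if strategy == "first_eligibility":
        index = first_elig
        for pid in m["patient_id"].unique():
            if pid in index.index:
                rows.append((pid, index[pid], strategy, arm[pid]))
            else:
                logger.warning("patient %s has no eligibility date; excluded", pid)
    else:
        starts = _first_enrolled_start(m).set_index("patient_id")["start_date"]
        if strategy == "shifted_eligibility":
            if mean_lag_days is None:
                mean_lag_days = mean_eligibility_to_enrollment_lag(labels, episodes)
            shift = pd.Timedelta(days=round(mean_lag_days))
        for pid in m["patient_id"].unique():
            if arm[pid] == "intervention":
                if pid not in starts.index:
                    logger.warning("enrolled patient %s has no start date; excluded", pid)
                    continue
                rows.append((pid, starts[pid], strategy, arm[pid]))
            else:
                if pid not in elig_pick.index:
                    logger.warning("patient %s has no eligibility date; excluded", pid)
                    continue
                date = elig_pick[pid]
                if strategy == "shifted_eligibility":
                    date = date + shift
                rows.append((pid, date, strategy, arm[pid]))
    return pd.DataFrame(rows, columns=["patient_id", "index_date", "strategy", "arm"])


def build_cross_sectional_cohorts(
    labels: pd.DataFrame,
    episodes: pd.DataFrame,
    index: pd.DataFrame,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> pd.DataFrame:
    """Assign each indexed patient to one of the four window cohorts.

    Precedence inside the half-open window ``[index, index + window_days)``:
    an enrolled episode *starting* in-window makes the patient a completed
    (episode end before window close) or incomplete enrollment; otherwise an
    opt-out episode in-window (its start date, or eligibility date when no
    start exists) makes the patient opt-out; otherwise not approached.
    Enrollment is intent-to-treat: completing, dropping out or remitting
    inside the episode does not change cohort membership.
    """
    m = _labelled(labels, episodes)
    idx = index.set_index("patient_id")["index_date"]
    missing_index = set(m["patient_id"]) - set(idx.index)
    if missing_index:
        raise ValueError(f"labelled patients without an index date: {sorted(missing_index)[:5]}")
    w = pd.Timedelta(days=window_days)
    rows = []
    for pid, grp in m.groupby("patient_id"):
        lo = idx[pid]
        hi = lo + w
        cohort = "not_approached_6m"
        enrolled = grp[
            (grp["status"] == "enrolled")
            & grp["start_date"].notna()
            & (grp["start_date"] >= lo)
            & (grp["start_date"] < hi)
        ]
        if len(enrolled):
            completed = enrolled[enrolled["end_date"].notna() & (enrolled["end_date"] < hi)]
            cohort = (
                "completed_enrollment_6m" if len(completed) else "incomplete_enrollment_6m"
            )
        else:
            opt = grp[grp["status"] == "opt_out"]
            anchor = opt["start_date"].fillna(opt["eligibility_date"])
            if ((anchor >= lo) & (anchor < hi)).any():
                cohort = "opt_out_6m"
        rows.append((pid, cohort, lo, hi))
    out = pd.DataFrame(
        rows, columns=["patient_id", "cohort", "window_start", "window_end"]
    )
    counts = {c: int((out["cohort"] == c).sum()) for c in COHORTS}
    logger.info("window cohorts (%d days): %s", window_days, counts)
    return out


def extract_window_records(
    bundle: RegistryBundle,
    index: pd.DataFrame,
    observation_days: int,
    outcome_days: int,
) -> dict[str, dict[str, dict[str, pd.DataFrame]]]:
    """Per-patient record slices for observation and outcome windows.

    Observation window is ``[index − observation_days, index)``; outcome
    window ``[index, index + outcome_days)`` — both half-open, so a record
    dated exactly at the index date falls into the outcome window.
    Episodes are sliced by eligibility date, contacts by contact date and
    questionnaires by recording date.
    """
    date_col = {
        "episodes": "eligibility_date",
        "contacts": "contact_date",
        "questionnaires": "recording_date",
    }
    out: dict[str, dict[str, dict[str, pd.DataFrame]]] = {}
    for row in index.itertuples():
        pid, lo = row.patient_id, row.index_date
        obs_lo = lo - pd.Timedelta(days=observation_days)
        out_hi = lo + pd.Timedelta(days=outcome_days)
        slices: dict[str, dict[str, pd.DataFrame]] = {"observation": {}, "outcome": {}}
        for table, col in date_col.items():
            df = bundle.table(table)
            mine = df[df["patient_id"] == pid]
            dates = mine[col]
            slices["observation"][table] = mine[
                dates.notna() & (dates >= obs_lo) & (dates < lo)
            ].copy()
            slices["outcome"][table] = mine[
                dates.notna() & (dates >= lo) & (dates < out_hi)
            ].copy()
        out[pid] = slices
    return out
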
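"""Domain model and delimited-text I/O for the four linked registry tables.

A collaborative-care depression registry is modelled as four tables:

* ``demographics`` — one row per patient (birth date, sex, race, marital
  status, employment status, consent and diagnosis flags).
* ``episodes`` — the care-coordination (CCM) table; one row per *patient
  instance*, i.e. one eligibility-to-end record.  A patient may own several
  episodes.  ``start_date`` may legitimately be missing (patient never
  approached).
* ``contacts`` — the care-coordinator contact log (contact date, minutes
  spent).
* ``questionnaires`` — instrument responses (PHQ-9 items and total, GAD-7,
  MDQ, AUDIT) with a recording date.

Tables are plain :class:`pandas.DataFrame` objects with documented columns;
:class:`RegistryBundle` groups them together with the cross-table linkage map
and orphan report produced by :func:`link_records`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

TABLES = ("demographics", "episodes", "contacts", "questionnaires")

PHQ9_ITEM_COLUMNS = tuple(f"item_{i}" for i in range(1, 10))

INSTRUMENTS = ("PHQ9", "GAD7", "MDQ", "AUDIT")

REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "demographics": (
        "patient_id",
        "birth_date",
        "sex",
        "race",
        "marital_status",
        "employment_status",
        "consent",
        "bipolar_history",
        "depression_diagnosis",
    ),
    "episodes": (
        "episode_id",
        "patient_id",
        "eligibility_date",
        "start_date",
        "end_date",
        "recorded_status",
    ),
    "contacts": ("patient_id", "contact_date", "time_spent"),
    "questionnaires": (
        ("patient_id", "instrument")
        + PHQ9_ITEM_COLUMNS
        + ("total", "recording_date")
    ),
}

DATE_COLUMNS: dict[str, tuple[str, ...]] = {
    "demographics": ("birth_date",),
    "episodes": ("eligibility_date", "start_date", "end_date"),
    "contacts": ("contact_date",),
    "questionnaires": ("recording_date",),
}

BOOL_COLUMNS: dict[str, tuple[str, ...]] = {
    "demographics": ("consent", "bipolar_history", "depression_diagnosis"),
}

INT_COLUMNS: dict[str, tuple[str, ...]] = {
    "contacts": ("time_spent",),
    "questionnaires": PHQ9_ITEM_COLUMNS + ("total",),
}

#: Sentinel used for a missing date inside a composite episode key.  A missing
#: start date is a legal key component (not-approached patient instances).
MISSING_KEY = "NA"

#: Optional bookkeeping column on the episode table recording where the start
#: date came from: "recorded" (present in the raw table), "missing", or
#: "recovered" (reconstructed from the contact log).
START_PROVENANCE_COLUMN = "start_provenance"


@dataclass(frozen=True)
class Dialect:
    """Delimited-text dialect: comma-separated, ISO-8601 dates by default."""

    delimiter: str = ","
    date_format: str = "%Y-%m-%d"


@dataclass(frozen=True)
class Episode:
    """One patient instance in the CCM table."""

    episode_id: str
    patient_id: str
    eligibility_date: pd.Timestamp | None
    start_date: pd.Timestamp | None
    end_date: pd.Timestamp | None
    recorded_status: str | None = None

    @classmethod
    def from_row(cls, row: pd.Series) -> "Episode":
        def _d(v):
            return None if pd.isna(v) else pd.Timestamp(v)

        rs = row.get("recorded_status")
        return cls(
            episode_id=row["episode_id"],
            patient_id=row["patient_id"],
            eligibility_date=_d(row["eligibility_date"]),
            start_date=_d(row["start_date"]),
            end_date=_d(row["end_date"]),
            recorded_status=None if pd.isna(rs) else str(rs),
        )


@dataclass
class RegistryBundle:
    """The four linked raw tables plus linkage map and orphan report."""

    demographics: pd.DataFrame
    episodes: pd.DataFrame
    contacts: pd.DataFrame
    questionnaires: pd.DataFrame
    linkage: pd.DataFrame | None = None
    orphans: dict[str, pd.DataFrame] = field(default_factory=dict)
    parse_log: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        if name not in TABLES:
            raise KeyError(f"unknown table {name!r}")
        return getattr(self, name)

    def set_table(self, name: str, df: pd.DataFrame) -> None:
        if name not in TABLES:
            raise KeyError(f"unknown table {name!r}")
        setattr(self, name, df)

    def copy(self) -> "RegistryBundle":
        return RegistryBundle(
            demographics=self.demographics.copy(),
            episodes=self.episodes.copy(),
            contacts=self.contacts.copy(),
            questionnaires=self.questionnaires.copy(),
            linkage=None if self.linkage is None else self.linkage.copy(),
            orphans={k: v.copy() for k, v in self.orphans.items()},
            parse_log=dict(self.parse_log),
        )

    @property
    def row_counts(self) -> dict[str, int]:
        return {t: len(self.table(t)) for t in TABLES}


def empty_bundle() -> RegistryBundle:
    """Schema-valid bundle with zero rows in every table."""
    tables = {}
    for t in TABLES:
        cols = list(REQUIRED_COLUMNS[t])
        df = pd.DataFrame({c: pd.Series(dtype="object") for c in cols})
        for c in DATE_COLUMNS[t]:
            df[c] = pd.Series(dtype="datetime64[ns]")
        for c in INT_COLUMNS.get(t, ()):
            df[c] = pd.Series(dtype="Int64")
        tables[t] = df
    tables["episodes"][START_PROVENANCE_COLUMN] = pd.Series(dtype="object")
    return RegistryBundle(**tables)


# ---------------------------------------------------------------------------
# Loading / writing
# ---------------------------------------------------------------------------

def _normalise_missing(df: pd.DataFrame) -> pd.DataFrame:
    return df.where(df.notna() & (df != ""), pd.NA)


_BOOL_MAP = {
    "true": True,
    "false": False,
    "yes": True,
    "no": False,
    "1": True,
    "0": False,
}


def _read_table(path: Path, table: str, dialect: Dialect) -> tuple[pd.DataFrame, int]:
    if not path.exists():
        raise FileNotFoundError(f"registry table file not found: {path}")
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    missing_cols = [c for c in REQUIRED_COLUMNS[table] if c not in df.columns]
    if missing_cols:
        raise ValueError(
            f"table {table!r} is missing mandatory column(s): {', '.join(missing_cols)}"
        )
    df = _normalise_missing(df)
    n_bad_dates = 0
    for c in DATE_COLUMNS[table]:
        parsed = pd.to_datetime(df[c], format=dialect.date_format, errors="coerce")
        bad = int((df[c].notna() & parsed.isna()).sum())
        if bad:
            logger.warning("%s.%s: %d unparseable date(s) set to missing", table, c, bad)
        n_bad_dates += bad
        df[c] = parsed
    for c in BOOL_COLUMNS.get(table, ()):
        df[c] = df[c].map(
            lambda v: pd.NA if pd.isna(v) else _BOOL_MAP.get(str(v).strip().lower(), pd.NA)
        )
    for c in INT_COLUMNS.get(table, ()):
        df[c] = pd.to_numeric(df[c], errors="coerce").astype("Int64")
    return df, n_bad_dates


def load_registry(
    source: Path | str | Mapping[str, Path | str],
    dialect: Dialect = Dialect(),
) -> RegistryBundle:
    """Load the four registry tables from delimited text.

    ``source`` is either a directory containing ``demographics.csv``,
    ``episodes.csv``, ``contacts.csv`` and ``questionnaires.csv``, or a
    mapping from table name to file path.  Unparseable dates become missing
    values and are logged; no rows are dropped at load time — all exclusions
    happen in later, logged pipeline stages.
    """
    if isinstance(source, (str, Path)):
        base = Path(source)
        paths = {t: base / f"{t}.csv" for t in TABLES}
    else:
        paths = {t: Path(source[t]) for t in TABLES}
    frames: dict[str, pd.DataFrame] = {}
    parse_log: dict[str, int] = {}
    for t in TABLES:
        frames[t], parse_log[t] = _read_table(paths[t], t, dialect)
        logger.info("loaded %s: %d rows", t, len(frames[t]))
    episodes = frames["episodes"]
    dup = episodes["episode_id"][episodes["episode_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate episode_id values: {sorted(set(dup))[:5]}")
    if START_PROVENANCE_COLUMN not in episodes.columns:
        episodes[START_PROVENANCE_COLUMN] = pd.Series(
            ["recorded" if ok else "missing" for ok in episodes["start_date"].notna()],
            index=episodes.index,
            dtype="object",
        )
    return RegistryBundle(parse_log=parse_log, **frames)


def write_registry(
    bundle: RegistryBundle,
    directory: Path | str,
    dialect: Dialect = Dialect(),
) -> dict[str, Path]:
    """Write the four tables as delimited text under ``directory``.

    Writing a cleanly loaded bundle and re-loading it is lossless
    (round-trip), which is covered by the test suite.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for t in TABLES:
        df = bundle.table(t).copy()
        for c in DATE_COLUMNS[t]:
            df[c] = df[c].dt.strftime(dialect.date_format)
        for c in BOOL_COLUMNS.get(t, ()):
            df[c] = df[c].map(lambda v: "" if pd.isna(v) else str(bool(v)))
        path = directory / f"{t}.csv"
        df.to_csv(path, sep=dialect.delimiter, index=False, na_rep="")
        paths[t] = path
    return paths


# ---------------------------------------------------------------------------
# Linkage
# ---------------------------------------------------------------------------

def composite_key(
    patient_id: str,
    eligibility_date,
    start_date,
    date_format: str = "%Y-%m-%d",
) -> str:
    """Composite episode key (patient id, eligibility date, start date).

    A missing date is encoded with the ``NA`` sentinel so that not-approached
    instances (missing start date) still carry a well-defined key.
    """

    def _fmt(d) -> str:
        return MISSING_KEY if pd.isna(d) else pd.Timestamp(d).strftime(date_format)

    return f"{patient_id}|{_fmt(eligibility_date)}|{_fmt(start_date)}"


def link_records(bundle: RegistryBundle) -> RegistryBundle:
    """Resolve cross-table linkage and report orphans.

    Populates ``bundle.linkage`` with one row per episode (episode id,
    patient id, composite key) and ``bundle.orphans`` with the child rows
    whose patient id does not resolve to a demographics row.  Orphans are a
    report, not a construction failure: the data-quality engine flags them.
    """
    out = bundle.copy()
    episodes = out.episodes
    linkage = pd.DataFrame(
        {
            "episode_id": episodes["episode_id"],
            "patient_id": episodes["patient_id"],
            "composite_key": [
                composite_key(r.patient_id, r.eligibility_date, r.start_date)
                for r in episodes.itertuples()
            ],
        },
        index=episodes.index,
    )
    known = set(out.demographics["patient_id"].dropna())
    orphans = {}
    for t in ("episodes", "contacts", "questionnaires"):
        df = out.table(t)
        mask = ~df["patient_id"].isin(known)
        orphans[t] = df[mask].copy()
        if mask.any():
            logger.warning("%s: %d orphan row(s) with unknown patient_id", t, int(mask.sum()))
    out.linkage = linkage
    out.orphans = orphans
    return out


def _attribute_events(
    events: pd.DataFrame, date_col: str, episodes: pd.DataFrame
) -> pd.Series:
    """Attribute dated child rows to episodes.

    A row belongs to an episode when its date falls inside the episode's
    closed ``[eligibility_date, end_date]`` interval for the same patient.
    When several episodes of one patient cover the date, the row is
    attributed to the episode with the latest eligibility date not after the
    event (ties broken by smallest episode id).  Returns a Series of episode
    ids aligned with ``events``; unattributable rows get ``pd.NA``.
    """
    out = pd.Series(pd.NA, index=events.index, dtype="object")
    if events.empty or episodes.empty:
        return out
    ev = events[["patient_id", date_col]].reset_index(names="_row")
    epi = episodes[["episode_id", "patient_id", "eligibility_date", "end_date"]]
    epi = epi.dropna(subset=["eligibility_date", "end_date"])
    m = ev.merge(epi, on="patient_id", how="inner")
    m = m[
        m[date_col].notna()
        & (m["eligibility_date"] <= m[date_col])
        & (m[date_col] <= m["end_date"])
    ]
    if m.empty:
        return out
    m = m.sort_values(
        ["_row", "eligibility_date", "episode_id"], ascending=[True, True, False]
    )
    best = m.groupby("_row").tail(1).set_index("_row")["episode_id"]
    out.loc[best.index] = best.to_numpy()
    return out


def attribute_contacts(bundle: RegistryBundle) -> pd.Series:
    """Episode id for every contact row (``pd.NA`` when unattributable)."""
    return _attribute_events(bundle.contacts, "contact_date", bundle.episodes)


def attribute_questionnaires(bundle: RegistryBundle) -> pd.Series:
    """Episode id for every questionnaire row (``pd.NA`` when unattributable)."""
    return _attribute_events(bundle.questionnaires, "recording_date", bundle.episodes)
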
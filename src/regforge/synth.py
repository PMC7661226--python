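"""Synthetic four-table registry bundles with planted ground truth.

The generator emulates the *structural* properties a registry-preparation
pipeline consumes — multi-episode patients, the enrolled/opt-out/
not-approached status mixture, missing start and end dates, contact-log
engagement, intake questionnaires — not clinical trajectories.  Every
generated bundle is clean by construction (the full data-quality ruleset
finds nothing), and :func:`inject_errors` corrupts a bundle with a known
ledger so detection can be scored exactly.

Planted semantics per status:

* ``enrolled`` — start date present, >=1 attributable contact with positive
  total minutes;
* ``opt_out`` — start date present (the offer), zero attributable contacts;
* ``not_approached`` — start date absent, no contacts;
* *recoverable* — planted as enrolled but emitted with the start date
  blanked; a contact sits exactly on the true start date, so the recovery
  procedure reconstructs it and classification returns ``enrolled``.

Episodes of one patient never overlap, so contact attribution is
unambiguous.  A single root seed drives independent substreams, and the same
(config, seed) pair reproduces the bundle byte for byte.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from . import model
from .model import RegistryBundle, START_PROVENANCE_COLUMN, PHQ9_ITEM_COLUMNS

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


class InjectionError(ValueError):
    pass


def _check_probs(name: str, probs) -> None:
    if any(p < 0 for p in probs):
        raise ConfigurationError(f"{name}: negative probability")
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name}: probabilities must sum to 1")


class GeneratorConfig(BaseModel):
    """Study conditions for a synthetic registry draw.

    Defaults emulate the marginals of a collaborative-care depression
    registry: ~44/33/22 status split, 23.4% missing start dates, 2008-2018
    date range, contact counts capped at 123 and per-contact minutes at 990.
    Distributional shapes beyond the published min/max (log-normal minutes
    and durations, Poisson contact counts) are pragmatic choices.
    """

    n_patients: int = Field(default=1000, ge=0)
    n_episodes: Optional[int] = Field(default=None, ge=0)
    episodes_per_patient: tuple[float, ...] = (0.85, 0.12, 0.03)
    status_mixture: tuple[float, float, float] = (0.4430, 0.3330, 0.2240)
    allocation: Literal["exact", "stochastic"] = "exact"
    missing_start_rate: float = Field(default=0.2342, ge=0.0, le=1.0)
    missing_end_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    recorded_status_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    date_min: date = date(2008, 3, 3)
    date_max: date = date(2018, 5, 17)
    max_activation_days: int = Field(default=1263, ge=1)
    mean_activation_days: float = Field(default=120.0, gt=0)
    max_eligibility_time_days: int = Field(default=900, ge=1)
    mean_contacts: float = Field(default=8.0, ge=1.0)
    max_contacts: int = Field(default=123, ge=1)
    mean_minutes: float = Field(default=20.0, gt=0)
    max_minutes_per_contact: int = Field(default=990, ge=1)
    severity_mixture: tuple[float, float, float] = (0.45, 0.35, 0.20)
    gad7_rate: float = Field(default=0.3, ge=0.0, le=1.0)
    female_rate: float = Field(default=0.715, ge=0.0, le=1.0)
    sex_missing_rate: float = Field(default=0.001, ge=0.0, le=1.0)
    race_freqs: dict[str, float] = Field(
        default_factory=lambda: {
            "White": 0.9198,
            "Black or African American": 0.0227,
            "Asian": 0.0168,
            "Native American": 0.0040,
            "Others": 0.0272,
            "Unknown": 0.0095,
        }
    )
    marital_freqs: dict[str, float] = Field(
        default_factory=lambda: {
            "Married": 0.4894,
            "Single": 0.3046,
            "Divorced": 0.1571,
            "Widowed": 0.0464,
            "Unknown": 0.0025,
        }
    )
    employment_freqs: dict[str, float] = Field(
        default_factory=lambda: {"yes": 0.55, "no": 0.40}
    )
    consent_rate: float = Field(default=1.0, ge=0.0, le=1.0)
    bipolar_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    age_mean: float = 41.3
    age_sd: float = 16.2
    age_min: int = Field(default=19, ge=19)
    age_max: int = 85

    @field_validator("episodes_per_patient", "status_mixture", "severity_mixture")
    @classmethod
    def _probs_sum(cls, v, info):
        _check_probs(info.field_name, v)
        return v

    @model_validator(mode="after")
    def _dates_and_freqs(self):
        if self.date_min >= self.date_max:
            raise ConfigurationError("date_min must precede date_max")
        if (self.date_max - self.date_min).days < 730:
            raise ConfigurationError("date range must span at least 730 days")
        for name in ("race_freqs", "marital_freqs", "employment_freqs"):
            freqs = getattr(self, name)
            total = sum(freqs.values())
            if total > 1.0 + 1e-9 or any(p < 0 for p in freqs.values()):
                raise ConfigurationError(f"{name}: frequencies must be >=0 and sum to <=1")
        return self


@dataclass
class GroundTruth:
    """Planted per-episode facts plus the injected-error ledger."""

    episodes: pd.DataFrame  # episode_id, patient_id, status, dropped, recoverable, true_start
    ledger: list[dict] = field(default_factory=list)

    def planted_status(self) -> pd.Series:
        """Status per non-dropped episode (Series indexed by episode_id)."""
        kept = self.episodes[~self.episodes["dropped"]]
        return kept.set_index("episode_id")["status"]

    def to_dict(self) -> dict:
        df = self.episodes.copy()
        df["true_start"] = df["true_start"].map(
            lambda v: None if pd.isna(v) else str(pd.Timestamp(v).date())
        )
        return {"episodes": df.to_dict(orient="records"), "ledger": list(self.ledger)}


STATUS_NAMES = ("enrolled", "opt_out", "not_approached")

_SEVERITY_BANDS = ((10, 14), (15, 19), (20, 27))

# Per-episode layout: lag <= 30 days, then duration, then a buffer before the
# next episode of the same patient; slots are spaced accordingly.
_SLOT_GAP = 120


def _allocate_exact(n: int, probs, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder integer allocation of n items over len(probs) bins."""
    raw = np.asarray(probs) * n
    quotas = np.floor(raw).astype(int)
    short = n - quotas.sum()
    order = np.argsort(-(raw - quotas), kind="stable")
    quotas[order[:short]] += 1
    out = np.repeat(np.arange(len(probs)), quotas)
    return rng.permutation(out)


def compose_phq9_items(total: int, rng: np.random.Generator) -> np.ndarray:
    """A random 9-vector of 0-3 items summing exactly to ``total``."""
    if not 0 <= total <= 27:
        raise ValueError(f"total {total} outside 0-27")
    items = np.minimum(rng.multinomial(total, [1 / 9] * 9), 3)
    while items.sum() < total:
        open_slots = np.flatnonzero(items < 3)
        items[rng.choice(open_slots)] += 1
    return items


def _duration(rng: np.random.Generator, mean: float, cap: int) -> int:
    if cap <= 0:
        return 0
    d = int(rng.lognormal(math.log(mean), 0.9))
    return int(min(max(d, 0), cap))


def generate_registry(
    config: GeneratorConfig, seed: int
) -> tuple[RegistryBundle, GroundTruth]:
    """Generate a clean four-table bundle plus its ground-truth ledger."""
    ss = np.random.SeedSequence(seed)
    r_demo, r_epi, r_contact, r_quest = (np.random.default_rng(s) for s in ss.spawn(4))

    # --- episodes per patient -------------------------------------------------
    k_max = len(config.episodes_per_patient)
    if config.n_patients == 0 and not config.n_episodes:
        return model.empty_bundle(), GroundTruth(
            episodes=pd.DataFrame(
                columns=[
                    "episode_id",
                    "patient_id",
                    "status",
                    "dropped",
                    "recoverable",
                    "true_start",
                ]
            )
        )
    counts = list(
        r_epi.choice(np.arange(1, k_max + 1), size=config.n_patients, p=config.episodes_per_patient)
    )
    if config.n_episodes is not None:
        while sum(counts) < config.n_episodes:
            counts.append(
                int(r_epi.choice(np.arange(1, k_max + 1), p=config.episodes_per_patient))
            )
        excess = sum(counts) - config.n_episodes
        while excess > 0:  # trim from the tail, dropping empty patients
            take = min(excess, counts[-1])
            counts[-1] -= take
            excess -= take
            if counts[-1] == 0:
                counts.pop()
    counts = [int(c) for c in counts]
    n_patients = len(counts)
    n_kept = sum(counts)

    # --- planted statuses -----------------------------------------------------
    if config.allocation == "exact":
        status_idx = _allocate_exact(n_kept, config.status_mixture, r_epi)
    else:
        status_idx = r_epi.choice(3, size=n_kept, p=config.status_mixture)
    n_na = int((status_idx == 2).sum())
    n_missing_target = int(round(config.missing_start_rate * n_kept))
    n_recover = max(0, n_missing_target - n_na)
    enrolled_positions = np.flatnonzero(status_idx == 0)
    if n_recover > len(enrolled_positions):
        raise ConfigurationError(
            "missing_start_rate exceeds what the status mixture can supply"
        )
    recoverable = np.zeros(n_kept, dtype=bool)
    if n_recover:
        recoverable[r_epi.choice(enrolled_positions, size=n_recover, replace=False)] = True
    recorded = np.zeros(n_kept, dtype=bool)
    if config.recorded_status_rate > 0:
        candidates = np.flatnonzero((status_idx <= 1) & ~recoverable)
        recorded[candidates] = r_epi.random(len(candidates)) < config.recorded_status_rate

    n_drop = int(round(config.missing_end_rate * n_kept))
    extra = np.zeros(n_patients, dtype=int)
    for p in r_epi.integers(0, n_patients, size=n_drop):
        extra[p] += 1

    # --- per-patient episode layout -------------------------------------------
    D = (config.date_max - config.date_min).days
    base = pd.Timestamp(config.date_min)

    epi_rows: list[tuple] = []  # eid, pid, elig_off, start_off, end_off, recorded_status, prov
    truth_rows: list[tuple] = []
    contact_rows: list[tuple] = []  # pid, day_off, minutes
    quest_specs: list[tuple] = []  # pid, day_off, instrument
    next_status = 0
    eid_counter = 0

    for p in range(n_patients):
        pid = f"P{p + 1:06d}"
        k_total = counts[p] + extra[p]
        room = D - _SLOT_GAP - _SLOT_GAP * k_total
        if room <= k_total:
            raise ConfigurationError("date range too short for the episode layout")
        offs = np.sort(r_epi.choice(room, size=k_total, replace=False)) + np.arange(
            k_total
        ) * _SLOT_GAP
        spans = np.diff(np.append(offs, D)).astype(int)
        for j in range(k_total):
            eid_counter += 1
            eid = f"E{eid_counter:06d}"
            elig = int(offs[j])
            span = int(spans[j])
            is_dropped = j >= counts[p]
            if is_dropped:
                status, is_recover, is_recorded = "enrolled", False, False
            else:
                status = STATUS_NAMES[status_idx[next_status]]
                is_recover = bool(recoverable[next_status])
                is_recorded = bool(recorded[next_status])
                next_status += 1
            rec_status = status if is_recorded else None
            if status == "not_approached":
                dur = max(1, _duration(r_epi, config.mean_activation_days,
                                       min(span - 2, config.max_eligibility_time_days)))
                epi_rows.append((eid, pid, elig, None, elig + dur, rec_status, "missing"))
                truth_rows.append((eid, pid, status, False, False, None))
                quest_specs.append((pid, elig, "PHQ9"))
                continue
            lag = int(r_epi.integers(0, 31))
            dur = _duration(
                r_epi,
                config.mean_activation_days,
                min(span - lag - 2, config.max_activation_days),
            )
            if is_recover and lag + dur == 0:
                dur = 1
            start = elig + lag
            end = start + dur
            if is_dropped:
                epi_rows.append((eid, pid, elig, start, None, None, "recorded"))
                truth_rows.append((eid, pid, status, True, False, start))
                quest_specs.append((pid, elig, "PHQ9"))
                quest_specs.append((pid, start, "PHQ9"))
                continue
            if status == "enrolled":
                c = int(np.clip(1 + r_contact.poisson(config.mean_contacts - 1.0),
                                1, config.max_contacts))
                c_offs = r_contact.integers(0, dur + 1, size=c)
                if is_recover:
                    c_offs[0] = 0
                minutes = np.clip(
                    np.round(r_contact.lognormal(math.log(config.mean_minutes), 0.8, size=c)),
                    0,
                    config.max_minutes_per_contact,
                ).astype(int)
                minutes[0] = max(1, minutes[0])
                for off, mins in zip(c_offs, minutes):
                    contact_rows.append((pid, start + int(off), int(mins)))
            if is_recover:
                epi_rows.append((eid, pid, elig, None, end, rec_status, "missing"))
                truth_rows.append((eid, pid, status, False, True, start))
            else:
                epi_rows.append((eid, pid, elig, start, end, rec_status, "recorded"))
                truth_rows.append((eid, pid, status, False, False, start))
            quest_specs.append((pid, elig, "PHQ9"))
            quest_specs.append((pid, start, "PHQ9"))
            if status == "enrolled" and r_quest.random() < config.gad7_rate:
                quest_specs.append((pid, elig, "GAD7"))

    # --- demographics ---------------------------------------------------------
    first_elig: dict[str, int] = {}
    for row in epi_rows:
        pid, elig = row[1], row[2]
        first_elig[pid] = min(first_elig.get(pid, D + 1), elig)
    pids = [f"P{p + 1:06d}" for p in range(n_patients)]
    ages = r_demo.normal(config.age_mean, config.age_sd, size=n_patients)
    for i in range(n_patients):  # truncated-normal resampling
        while not (config.age_min <= ages[i] <= config.age_max):
            ages[i] = r_demo.normal(config.age_mean, config.age_sd)

    def _cat(freqs: dict[str, float], n: int, rng) -> list:
        names = list(freqs) + [None]
        probs = list(freqs.values())
        probs.append(max(0.0, 1.0 - sum(probs)))
        probs = np.asarray(probs) / sum(probs)
        picks = rng.choice(len(names), size=n, p=probs)
        return [names[i] for i in picks]

    sex_probs = {
        "female": config.female_rate,
        "male": max(0.0, 1.0 - config.female_rate - config.sex_missing_rate),
    }
    demo = pd.DataFrame(
        {
            "patient_id": pids,
            "birth_date": [
                base
                + pd.Timedelta(days=int(first_elig.get(pids[i], 0)))
                - pd.Timedelta(days=int(round(ages[i] * 365.25)))
                for i in range(n_patients)
            ],
            "sex": _cat(sex_probs, n_patients, r_demo),
            "race": _cat(config.race_freqs, n_patients, r_demo),
            "marital_status": _cat(config.marital_freqs, n_patients, r_demo),
            "employment_status": _cat(config.employment_freqs, n_patients, r_demo),
            "consent": r_demo.random(n_patients) < config.consent_rate,
            "bipolar_history": r_demo.random(n_patients) < config.bipolar_rate,
            "depression_diagnosis": np.ones(n_patients, dtype=bool),
        }
    )
    for c in ("consent", "bipolar_history", "depression_diagnosis"):
        demo[c] = demo[c].astype(object)
    demo["sex"] = demo["sex"].where(pd.notna(demo["sex"]), pd.NA)

    # --- episodes -------------------------------------------------------------
    def _dates(offs: list) -> pd.Series:
        return pd.Series(
            [pd.NaT if o is None or pd.isna(o) else base + pd.Timedelta(days=int(o)) for o in offs],
            dtype="datetime64[ns]",
        )

    episodes = pd.DataFrame(
        {
            "episode_id": [r[0] for r in epi_rows],
            "patient_id": [r[1] for r in epi_rows],
            "eligibility_date": _dates([r[2] for r in epi_rows]),
            "start_date": _dates([r[3] for r in epi_rows]),
            "end_date": _dates([r[4] for r in epi_rows]),
            "recorded_status": pd.Series([r[5] for r in epi_rows], dtype="object"),
            START_PROVENANCE_COLUMN: [r[6] for r in epi_rows],
        }
    )

    contacts = pd.DataFrame(
        {
            "patient_id": [r[0] for r in contact_rows],
            "contact_date": _dates([r[1] for r in contact_rows]),
            "time_spent": pd.array([r[2] for r in contact_rows], dtype="Int64"),
        }
    )

    # --- questionnaires -------------------------------------------------------
    q_rows = []
    for pid, off, instrument in quest_specs:
        if instrument == "PHQ9":
            band = _SEVERITY_BANDS[r_quest.choice(3, p=config.severity_mixture)]
            total = int(r_quest.integers(band[0], band[1] + 1))
            items = compose_phq9_items(total, r_quest)
            q_rows.append((pid, "PHQ9", *items.tolist(), total, off))
        else:
            total = int(r_quest.integers(0, 22))
            q_rows.append((pid, instrument, *([None] * 9), total, off))
    quest = pd.DataFrame(
        q_rows,
        columns=["patient_id", "instrument", *PHQ9_ITEM_COLUMNS, "total", "recording_date"],
    )
    for c in PHQ9_ITEM_COLUMNS + ("total",):
        quest[c] = pd.array(
            [pd.NA if pd.isna(v) else int(v) for v in quest[c]], dtype="Int64"
        )
    quest["recording_date"] = _dates(quest["recording_date"].tolist())

    bundle = RegistryBundle(
        demographics=demo, episodes=episodes, contacts=contacts, questionnaires=quest
    )
    truth = GroundTruth(
        episodes=pd.DataFrame(
            truth_rows,
            columns=["episode_id", "patient_id", "status", "dropped", "recoverable", "true_start"],
        ).assign(
            true_start=lambda df: _dates(df["true_start"].tolist())
        )
    )
    logger.info(
        "generated registry: %d patients, %d episodes (%d dropped-planted, %d recoverable)",
        n_patients,
        len(episodes),
        n_drop,
        n_recover,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------

ERROR_KINDS = (
    "phq_item_out_of_domain",
    "employment_free_text",
    "duplicate_episode_key",
    "date_inversion",
    "end_without_eligibility",
    "total_sum_mismatch",
)

_KIND_FAMILY = {
    "phq_item_out_of_domain": "attribute_domain",
    "employment_free_text": "attribute_domain",
    "duplicate_episode_key": "relational_integrity",
    "date_inversion": "historical_data",
    "end_without_eligibility": "state_dependent",
    "total_sum_mismatch": "attribute_dependency",
}

_FREE_TEXT = ("I am employed", "I am looking for a job")


class ErrorConfig(BaseModel):
    """How many violations to inject per error kind."""

    phq_item_out_of_domain: int = Field(default=1, ge=0)
    employment_free_text: int = Field(default=1, ge=0)
    duplicate_episode_key: int = Field(default=1, ge=0)
    date_inversion: int = Field(default=1, ge=0)
    end_without_eligibility: int = Field(default=1, ge=0)
    total_sum_mismatch: int = Field(default=1, ge=0)

    @classmethod
    def uniform(cls, n: int) -> "ErrorConfig":
        return cls(**{k: n for k in ERROR_KINDS})

    def count(self, kind: str) -> int:
        return getattr(self, kind)


def inject_errors(
    bundle: RegistryBundle, error_config: ErrorConfig, seed: int
) -> tuple[RegistryBundle, list[dict]]:
    """Corrupt a clean bundle with a known ledger of planted violations.

    Injections never collide on the same cell; PHQ-9 item and total/sum
    injections use disjoint questionnaire rows so each stays independently
    detectable after domain repairs.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    out = bundle.copy()
    ledger: list[dict] = []

    def _entry(kind, table, row_key, column, original, injected):
        ledger.append(
            {
                "kind": kind,
                "family": _KIND_FAMILY[kind],
                "table": table,
                "row_key": str(row_key),
                "column": column,
                "original": None if original is None or pd.isna(original) else str(original),
                "injected": None if injected is None else str(injected),
            }
        )

    quest = out.questionnaires
    phq_idx = quest.index[
        (quest["instrument"] == "PHQ9")
        & quest[list(PHQ9_ITEM_COLUMNS)].notna().all(axis=1)
        & quest["total"].notna()
    ]
    need_q = error_config.count("phq_item_out_of_domain") + error_config.count(
        "total_sum_mismatch"
    )
    if need_q > len(phq_idx):
        raise InjectionError("not enough complete PHQ-9 rows for requested injections")
    chosen_q = rng.choice(phq_idx, size=need_q, replace=False) if need_q else []
    n_item = error_config.count("phq_item_out_of_domain")
    for idx in chosen_q[:n_item]:
        col = PHQ9_ITEM_COLUMNS[rng.integers(0, 9)]
        bad = int(rng.choice([-1, 4, 5, 7]))
        _entry(
            "phq_item_out_of_domain", "questionnaires", f"questionnaires:{idx}",
            col, quest.at[idx, col], bad,
        )
        quest.at[idx, col] = bad
    for idx in chosen_q[n_item:]:
        true_total = int(quest.at[idx, "total"])
        delta = int(rng.integers(1, 6))
        bad = true_total + delta if true_total + delta <= 27 else true_total - delta
        _entry(
            "total_sum_mismatch", "questionnaires", f"questionnaires:{idx}",
            "total", true_total, bad,
        )
        quest.at[idx, "total"] = bad

    demo = out.demographics
    emp_idx = demo.index[demo["employment_status"].isin(["yes", "no"])]
    n_emp = error_config.count("employment_free_text")
    if n_emp > len(emp_idx):
        raise InjectionError("not enough employment answers for requested injections")
    for idx in rng.choice(emp_idx, size=n_emp, replace=False) if n_emp else []:
        text = _FREE_TEXT[int(rng.integers(0, len(_FREE_TEXT)))]
        _entry(
            "employment_free_text", "demographics", demo.at[idx, "patient_id"],
            "employment_status", demo.at[idx, "employment_status"], text,
        )
        demo.at[idx, "employment_status"] = text

    episodes = out.episodes
    inv_ok = episodes.index[
        episodes["start_date"].notna() & episodes["end_date"].notna()
    ]
    n_dup = error_config.count("duplicate_episode_key")
    n_inv = error_config.count("date_inversion")
    n_noelig = error_config.count("end_without_eligibility")
    noelig_ok = episodes.index[
        episodes["end_date"].notna() & episodes["eligibility_date"].notna()
    ]
    pool = list(episodes.index)
    rng.shuffle(pool)
    dup_rows, inv_rows, noelig_rows = [], [], []
    for idx in pool:
        if len(dup_rows) < n_dup:
            dup_rows.append(idx)
        elif len(inv_rows) < n_inv and idx in inv_ok:
            inv_rows.append(idx)
        elif len(noelig_rows) < n_noelig and idx in noelig_ok:
            noelig_rows.append(idx)
    if len(dup_rows) < n_dup or len(inv_rows) < n_inv or len(noelig_rows) < n_noelig:
        raise InjectionError("not enough episodes for requested injections")

    new_rows = []
    for k, idx in enumerate(dup_rows):
        row = episodes.loc[idx].copy()
        new_id = f"EDUP{k + 1:04d}"
        _entry(
            "duplicate_episode_key", "episodes", new_id,
            None, episodes.at[idx, "episode_id"], new_id,
        )
        row["episode_id"] = new_id
        new_rows.append(row)
    for idx in inv_rows:
        start = episodes.at[idx, "start_date"]
        bad_end = start - pd.Timedelta(days=int(rng.integers(1, 31)))
        _entry(
            "date_inversion", "episodes", episodes.at[idx, "episode_id"],
            "end_date", episodes.at[idx, "end_date"].date(), bad_end.date(),
        )
        episodes.at[idx, "end_date"] = bad_end
    for idx in noelig_rows:
        _entry(
            "end_without_eligibility", "episodes", episodes.at[idx, "episode_id"],
            "eligibility_date", episodes.at[idx, "eligibility_date"].date(), None,
        )
        episodes.at[idx, "eligibility_date"] = pd.NaT
    if new_rows:
        out.episodes = pd.concat(
            [episodes, pd.DataFrame(new_rows)], ignore_index=True
        )
    logger.info("injected %d violation(s)", len(ledger))
    return out, ledger


def ledger_recall(violations, ledger: list[dict]) -> tuple[int, list[dict]]:
    """How many ledger entries are matched by at least one violation.

    A match requires the same rule family, table and row key.  Returns
    (n_matched, unmatched_entries).
    """
    seen = {(v.family, v.table, str(v.row_key)) for v in violations}
    misses = [
        e for e in ledger if (e["family"], e["table"], e["row_key"]) not in seen
    ]
    return len(ledger) - len(misses), misses


def paper_profile_config() -> GeneratorConfig:
    """Generator profile matching the published registry marginals.

    15,576 eligible patient instances, status mixture 44.30/33.30/22.40,
    23.42% missing start dates, eligibility dates spanning 2008-03-03 to
    2018-05-17, contact counts capped at 123 and per-contact minutes at 990,
    with the missing-end rate implied by 90 dropped of 18,716 instances.
    Allocation is stochastic: each episode draws its status independently.
    """
    return GeneratorConfig(
        n_patients=13200,
        n_episodes=15576,
        status_mixture=(0.4430, 0.3330, 0.2240),
        allocation="stochastic",
        missing_start_rate=0.2342,
        missing_end_rate=90 / 18716,
        date_min=date(2008, 3, 3),
        date_max=date(2018, 5, 17),
        max_activation_days=1263,
        max_eligibility_time_days=900,
        max_contacts=123,
        max_minutes_per_contact=990,
    )
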
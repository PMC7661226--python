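"""Shared fixtures: hand-built miniature registry bundles."""

from __future__ import annotations

import pandas as pd
import pytest

from regforge import model
from regforge.model import PHQ9_ITEM_COLUMNS, RegistryBundle

DEMO_DEFAULTS = {
    "birth_date": "1980-01-15",
    "sex": "female",
    "race": "White",
    "marital_status": "Married",
    "employment_status": "yes",
    "consent": True,
    "bipolar_history": False,
    "depression_diagnosis": True,
}


def phq9(patient_id: str, recording_date: str, total: int, items=None) -> dict:
    """A PHQ-9 questionnaire row; items default to a valid 9-way split."""
    if items is None:
        items = [min(3, max(0, total - 3 * i)) for i in range(9)]
        deficit = total - sum(items)
        j = 0
        while deficit > 0:
            if items[j] < 3:
                items[j] += 1
                deficit -= 1
            else:
                j += 1
    row = {
        "patient_id": patient_id,
        "instrument": "PHQ9",
        "total": total,
        "recording_date": recording_date,
    }
    row.update({c: v for c, v in zip(PHQ9_ITEM_COLUMNS, items)})
    return row


def make_bundle(
    episodes: list[dict],
    contacts: list[dict] = (),
    questionnaires: list[dict] = (),
    demographics: list[dict] | None = None,
) -> RegistryBundle:
    """Build a schema-complete bundle from sparse row dicts.

    Demographics default to one clean consenting adult row per patient id
    seen in the episode table.
    """
    if demographics is None:
        pids = list(dict.fromkeys(e["patient_id"] for e in episodes))
        demographics = [{"patient_id": pid} for pid in pids]
    demographics = [{**DEMO_DEFAULTS, **d} for d in demographics]
    episodes = [{"recorded_status": None, **e} for e in episodes]

    frames = {}
    for name, rows in (
        ("demographics", demographics),
        ("episodes", episodes),
        ("contacts", list(contacts)),
        ("questionnaires", list(questionnaires)),
    ):
        cols = list(model.REQUIRED_COLUMNS[name])
        df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
        for c in model.DATE_COLUMNS[name]:
            df[c] = pd.to_datetime(df[c]) if len(df) else pd.Series(dtype="datetime64[ns]")
        for c in model.INT_COLUMNS.get(name, ()):
            df[c] = pd.array(
                [pd.NA if pd.isna(v) else int(v) for v in df[c]], dtype="Int64"
            )
        frames[name] = df
    epi = frames["episodes"]
    epi[model.START_PROVENANCE_COLUMN] = [
        "recorded" if ok else "missing" for ok in epi["start_date"].notna()
    ]
    return RegistryBundle(**frames)


@pytest.fixture
def simple_bundle() -> RegistryBundle:
    """One enrolled-style, one opt-out-style, one never-approached episode."""
    return make_bundle(
        episodes=[
            {"episode_id": "E1", "patient_id": "P1",
             "eligibility_date": "2010-01-01", "start_date": "2010-01-10",
             "end_date": "2010-06-01"},
            {"episode_id": "E2", "patient_id": "P2",
             "eligibility_date": "2011-02-01", "start_date": "2011-02-15",
             "end_date": "2011-05-01"},
            {"episode_id": "E3", "patient_id": "P3",
             "eligibility_date": "2012-03-01", "start_date": None,
             "end_date": "2012-09-01"},
        ],
        contacts=[
            {"patient_id": "P1", "contact_date": "2010-02-01", "time_spent": 30},
            {"patient_id": "P1", "contact_date": "2010-03-01", "time_spent": 15},
        ],
        questionnaires=[
            phq9("P1", "2010-01-01", 15),
            phq9("P2", "2011-02-01", 12),
            phq9("P3", "2012-03-01", 20),
        ],
    )
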
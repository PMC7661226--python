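"""Independent brute-force re-derivations used as test oracles.

These scan every row pairwise with plain Python loops, re-deriving contact
attribution, episode metrics and window-cohort assignment from their
definitions — deliberately sharing no code with the vectorised
implementations they check.
"""

from __future__ import annotations

import pandas as pd


def brute_attribution(contact, episodes: pd.DataFrame):
    """Episode id owning one dated contact row, or None."""
    candidates = []
    for e in episodes.itertuples():
        if (
            e.patient_id == contact.patient_id
            and pd.notna(e.eligibility_date)
            and pd.notna(e.end_date)
            and pd.notna(contact.contact_date)
            and e.eligibility_date <= contact.contact_date <= e.end_date
        ):
            candidates.append(e)
    if not candidates:
        return None
    best = sorted(candidates, key=lambda x: (-x.eligibility_date.value, x.episode_id))[0]
    return best.episode_id


def brute_episode_metrics(
    episodes: pd.DataFrame, contacts: pd.DataFrame, provenance: dict[str, str]
) -> dict[str, dict]:
    """Per-episode metrics by exhaustive contact scan."""
    per_episode: dict[str, list] = {}
    for c in contacts.itertuples():
        eid = brute_attribution(c, episodes)
        if eid is not None:
            per_episode.setdefault(eid, []).append(c)
    out = {}
    for e in episodes.itertuples():
        if pd.isna(e.end_date):
            continue
        mine = per_episode.get(e.episode_id, [])
        freq = len(mine)
        total = int(sum(int(c.time_spent) for c in mine))
        activation = eligibility = ce = None
        if pd.notna(e.start_date):
            activation = int((e.end_date - e.start_date).days)
        elif pd.notna(e.eligibility_date):
            eligibility = int((e.end_date - e.eligibility_date).days)
        if provenance.get(e.episode_id) == "recovered" and mine:
            first = min(c.contact_date for c in mine)
            ce = int((e.end_date - first).days)
        out[e.episode_id] = {
            "activation_time_days": activation,
            "eligibility_time_days": eligibility,
            "ce_time_days": ce,
            "contact_frequency": freq,
            "total_time_spent_min": total,
        }
    return out


def brute_window_cohort(
    labels: pd.DataFrame,
    episodes: pd.DataFrame,
    index: pd.DataFrame,
    window_days: int,
) -> dict[str, str]:
    """Four-cohort assignment by per-patient episode enumeration."""
    status = labels.set_index("episode_id")["status"]
    idx = index.set_index("patient_id")["index_date"]
    out = {}
    for pid in idx.index:
        lo = idx[pid]
        hi = lo + pd.Timedelta(days=window_days)
        completed = incomplete = opted = False
        for e in episodes.itertuples():
            if e.patient_id != pid or e.episode_id not in status.index:
                continue
            s = status[e.episode_id]
            if s == "enrolled" and pd.notna(e.start_date) and lo <= e.start_date < hi:
                if pd.notna(e.end_date) and e.end_date < hi:
                    completed = True
                else:
                    incomplete = True
            elif s == "opt_out":
                anchor = e.start_date if pd.notna(e.start_date) else e.eligibility_date
                if pd.notna(anchor) and lo <= anchor < hi:
                    opted = True
        if completed:
            out[pid] = "completed_enrollment_6m"
        elif incomplete:
            out[pid] = "incomplete_enrollment_6m"
        elif opted:
            out[pid] = "opt_out_6m"
        else:
            out[pid] = "not_approached_6m"
    return out
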
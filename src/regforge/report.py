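"""Subgroup summary tables and data-flow-diagram (DFD) emission.

``summarize_cohorts`` produces the registry's standard subgroup summary:
per status (enrolled / opt-out / not-approached) the instance count and
share, age mean/SD, sex/race/marital frequencies with explicit missing
rows, and PHQ-9 severity-band counts anchored at the start date and at the
eligibility date.  Start-date bands are reported as unavailable for the
not-approached column (no start date exists).

``build_flow_summary`` turns pipeline tallies into an attrition flow —
registry total, consent exclusion, criteria exclusion, the three statuses
and optional post-enrollment outcomes — checks count conservation at every
split, and emits the flow as DOT digraph text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohorts as cohorts_mod
from .cohorts import PHQ9_BANDS, STATUSES, band_phq9
from .model import RegistryBundle

logger = logging.getLogger(__name__)


class FlowConservationError(ValueError):
    """Child-node counts do not sum to their parent at some split."""


#: Parent -> children splits of the flow, applied when all keys are present.
FLOW_SPLITS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("registry_total", ("excluded_missing_end", "analyzable")),
    ("analyzable", ("consent_excluded", "consented")),
    ("consented", ("criteria_excluded", "eligible")),
    ("eligible", ("enrolled", "opt_out", "not_approached")),
    ("enrolled", ("drop_out", "remitted", "discharged")),
)


@dataclass(frozen=True)
class FlowSummary:
    nodes: tuple[tuple[str, int], ...]
    edges: tuple[tuple[str, str], ...]

    def counts(self) -> dict[str, int]:
        return dict(self.nodes)

    def validate(self) -> None:
        counts = self.counts()
        children: dict[str, list[str]] = {}
        for parent, child in self.edges:
            children.setdefault(parent, []).append(child)
        for parent, kids in children.items():
            total = sum(counts[k] for k in kids)
            if total != counts[parent]:
                raise FlowConservationError(
                    f"split {parent!r} -> {kids}: children sum to {total}, "
                    f"parent is {counts[parent]}"
                )

    def to_dot(self) -> str:
        lines = ["digraph registry_flow {", "  node [shape=box];"]
        for name, count in self.nodes:
            lines.append(f'  "{name}" [label="{name}\\n({count})"];')
        for parent, child in self.edges:
            lines.append(f'  "{parent}" -> "{child}";')
        lines.append("}")
        return "\n".join(lines)


def build_flow_summary(tallies: dict[str, int]) -> FlowSummary:
    """Flow summary from pipeline tallies; conservation-checked on build.

    ``tallies`` maps node names (see :data:`FLOW_SPLITS`) to counts; splits
    whose children are absent are skipped, so a minimal
    ``{"registry_total": 0}`` is valid.
    """
    if "registry_total" not in tallies:
        raise ValueError("tallies must include 'registry_total'")
    nodes: dict[str, int] = {"registry_total": int(tallies["registry_total"])}
    edges: list[tuple[str, str]] = []
    for parent, kids in FLOW_SPLITS:
        if parent not in nodes and parent not in tallies:
            continue
        if not all(k in tallies for k in kids):
            continue
        nodes.setdefault(parent, int(tallies[parent]))
        for k in kids:
            nodes[k] = int(tallies[k])
            edges.append((parent, k))
    summary = FlowSummary(nodes=tuple(nodes.items()), edges=tuple(edges))
    summary.validate()
    return summary


def emit_flow_summary(tallies: dict[str, int]) -> tuple[FlowSummary, str]:
    summary = build_flow_summary(tallies)
    return summary, summary.to_dot()


# ---------------------------------------------------------------------------
# Subgroup summary
# ---------------------------------------------------------------------------

def _round_half_up(x: float, digits: int = 2) -> float:
    scale = 10**digits
    return np.floor(x * scale + 0.5) / scale


def _freq_block(values: pd.Series, categories: list[str]) -> dict[str, dict]:
    n = len(values)
    out = {}
    observed = values.fillna("missing")
    for cat in categories + ["missing"]:
        count = int((observed == cat).sum())
        out[cat] = {"n": count, "pct": _round_half_up(100 * count / n) if n else 0.0}
    return out


def summarize_cohorts(
    labels: pd.DataFrame, bundle: RegistryBundle
) -> dict[str, dict]:
    """Per-status subgroup summary (counts, shares, demographics, PHQ bands).

    Percentages are printed to two decimals, rounded half-up; age SD uses
    the sample (n−1) convention.  The PHQ-9-at-start block for the
    not-approached column is reported as ``"not available"``.
    """
    m = labels.merge(bundle.episodes, on="episode_id", how="left")
    m = m.merge(
        bundle.demographics.drop_duplicates("patient_id"), on="patient_id", how="left"
    )
    phq_start = cohorts_mod.baseline_phq9(bundle, anchor="start_date")
    phq_elig = cohorts_mod.baseline_phq9(bundle, anchor="eligibility_date")
    epi_index = bundle.episodes.reset_index().set_index("episode_id")["index"]
    total = len(m)
    summary: dict[str, dict] = {}
    for status in STATUSES:
        grp = m[m["status"] == status]
        n = len(grp)
        entry: dict = {
            "n": n,
            "pct": _round_half_up(100 * n / total) if total else 0.0,
        }
        ages = [
            cohorts_mod._age_at(r.eligibility_date, r.birth_date)
            for r in grp.itertuples()
            if pd.notna(r.eligibility_date) and pd.notna(r.birth_date)
        ]
        entry["age_mean"] = _round_half_up(float(np.mean(ages))) if ages else None
        entry["age_sd"] = (
            _round_half_up(float(np.std(ages, ddof=1))) if len(ages) > 1 else None
        )
        entry["sex"] = _freq_block(grp["sex"], ["female", "male"])
        entry["race"] = _freq_block(
            grp["race"],
            ["White", "Black or African American", "Asian", "Native American",
             "Others", "Unknown"],
        )
        entry["marital_status"] = _freq_block(
            grp["marital_status"], ["Married", "Single", "Divorced", "Widowed", "Unknown"]
        )
        rows = epi_index.loc[grp["episode_id"]].to_numpy()
        if status == "not_approached":
            entry["phq9_at_start"] = "not available"
        else:
            bands = [band_phq9(s) for s in phq_start.loc[rows]]
            entry["phq9_at_start"] = {
                b: int(sum(x == b for x in bands)) for b in PHQ9_BANDS
            }
        bands = [band_phq9(s) for s in phq_elig.loc[rows]]
        entry["phq9_at_eligibility"] = {
            b: int(sum(x == b for x in bands)) for b in PHQ9_BANDS
        }
        summary[status] = entry
    return summary
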
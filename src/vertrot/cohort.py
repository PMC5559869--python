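"""Cohort-level aggregation of rotation change records.

Collects per-patient change records into the level-by-patient change
matrix, summarizes the junctions between the fused construct and the
adjacent un-instrumented spine (the en-bloc assessment), counts patients
with at least one significant change, and reports patients excluded for
unresolvable measurement ambiguity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .rotation import LEVEL_ORDER, RotationChangeRecord, SpineStudy, disc_key, study_change_records

__all__ = [
    "JunctionCategory",
    "CohortSummary",
    "records_to_frame",
    "build_change_matrix",
    "junction_summary",
    "count_patients_with_change",
    "exclusion_report",
    "summarize_cohort",
]

JUNCTION_CATEGORIES = (
    "adjacent_superior_vertebra",
    "adjacent_inferior_vertebra",
    "adjacent_superior_disc",
    "adjacent_inferior_disc",
    "apex",
)

# cephalad-to-caudal ordering over vertebra and disc keys, for matrix rows
_ENTITY_ORDER: list[str] = []
for _i, _lvl in enumerate(LEVEL_ORDER):
    _ENTITY_ORDER.append(_lvl)
    if _i + 1 < len(LEVEL_ORDER):
        _ENTITY_ORDER.append(disc_key(_lvl, LEVEL_ORDER[_i + 1]))
_ENTITY_RANK = {k: i for i, k in enumerate(_ENTITY_ORDER)}


@dataclass
class JunctionCategory:
    """Mean (and range) of changes in one junction category across patients."""

    mean: float
    min: float
    max: float
    n: int


@dataclass
class CohortSummary:
    """Cohort-level outputs: counts, junction summaries and the change matrix."""

    n_patients: int
    n_excluded: int
    exclusions: list[dict] = field(default_factory=list)
    patients_with_significant_change: int = 0
    junction_means: dict = field(default_factory=dict)  # category -> JunctionCategory
    en_bloc_detected: bool = False
    en_bloc_direction: Optional[int] = None  # sign of the construct rotation, if detected
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "n_patients": self.n_patients,
            "n_excluded": self.n_excluded,
            "exclusions": self.exclusions,
            "patients_with_significant_change": self.patients_with_significant_change,
            "junction_means": {k: asdict(v) for k, v in self.junction_means.items()},
            "en_bloc_detected": self.en_bloc_detected,
            "en_bloc_direction": self.en_bloc_direction,
            "records": self.records.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=indent, sort_keys=True)


def records_to_frame(records: Iterable[RotationChangeRecord]) -> pd.DataFrame:
    """Long-format table of change records (one row per patient x entity)."""
    rows = [
        {
            "patient": r.patient,
            "level_key": r.level_key,
            "kind": r.kind,
            "value_t1": r.value_t1,
            "value_t2": r.value_t2,
            "change": r.change,
            "significant": r.significant,
            "direction_vs_apex": r.direction_vs_apex,
            "loss_of_correction": r.loss_of_correction,
            "instrumented": r.instrumented,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient", "level_key", "kind", "value_t1", "value_t2", "change",
            "significant", "direction_vs_apex", "loss_of_correction", "instrumented",
        ],
    )


def build_change_matrix(records: Iterable[RotationChangeRecord]) -> dict[str, pd.DataFrame]:
    """Anatomical-level x patient grids of changes, significance and instrumentation.

    Rows are the union of entity keys across patients, ordered cephalad
    to caudal; cells not measured for a patient are NaN.  Duplicate
    (patient, level_key) records raise :class:`DataError`.
    """
    frame = records_to_frame(records)
    if frame.empty:
        return {
            "change": pd.DataFrame(),
            "significant": pd.DataFrame(),
            "instrumented": pd.DataFrame(),
        }
    dup = frame.duplicated(subset=["patient", "level_key"])
    if dup.any():
        bad = frame.loc[dup, ["patient", "level_key"]].iloc[0]
        raise DataError(f"duplicate record for {bad.patient} at {bad.level_key}")
    order = sorted(frame["level_key"].unique(), key=lambda k: _ENTITY_RANK[k])
    out = {}
    for col in ("change", "significant", "instrumented"):
        out[col] = (
            frame.pivot(index="level_key", columns="patient", values=col).reindex(order)
        )
    return out


def _study_junction_keys(study: SpineStudy) -> dict[str, str]:
    top, bottom = study.instrumented_range
    return {
        "adjacent_superior_vertebra": study.levels[0],
        "adjacent_inferior_vertebra": study.levels[-1],
        "adjacent_superior_disc": disc_key(study.levels[0], top),
        "adjacent_inferior_disc": disc_key(bottom, study.levels[-1]),
        "apex": study.apex,
    }


def junction_summary(
    studies: list[SpineStudy],
    records_by_patient: dict[str, list[RotationChangeRecord]],
    limit: float,
) -> tuple[dict[str, JunctionCategory], bool, Optional[int], list[dict]]:
    """Mean junction changes and the en-bloc verdict.

    En-bloc movement of the construct by delta appears as mean changes of
    -delta at the superior junction disc and +delta at the inferior one;
    it is declared detected when both junction-disc mean changes exceed
    the limit in magnitude with those opposite, construct-consistent
    signs.  Studies missing a junction entity are excluded from that
    category's mean and noted.
    """
    if limit <= 0:
        raise ParameterError("limit must be positive")
    values: dict[str, list[float]] = {k: [] for k in JUNCTION_CATEGORIES}
    notes = []
    for study in studies:
        recs = {r.level_key: r for r in records_by_patient.get(study.patient, [])}
        for category, key in _study_junction_keys(study).items():
            rec = recs.get(key)
            if rec is None:
                notes.append(
                    {"patient": study.patient, "category": category, "level_key": key,
                     "note": "missing record; excluded from category mean"}
                )
                continue
            values[category].append(rec.change)
    summary = {}
    for category, vals in values.items():
        if vals:
            arr = np.asarray(vals)
            summary[category] = JunctionCategory(
                mean=float(arr.mean()), min=float(arr.min()), max=float(arr.max()), n=arr.size
            )
        else:
            summary[category] = JunctionCategory(mean=float("nan"), min=float("nan"),
                                                 max=float("nan"), n=0)
    sup = summary["adjacent_superior_disc"]
    inf = summary["adjacent_inferior_disc"]
    detected = (
        sup.n > 0 and inf.n > 0
        and abs(sup.mean) > limit and abs(inf.mean) > limit
        and np.sign(sup.mean) == -np.sign(inf.mean)
    )
    direction = int(np.sign(inf.mean)) if detected else None
    return summary, bool(detected), direction, notes


def count_patients_with_change(records_by_patient: dict[str, list[RotationChangeRecord]]) -> int:
    """Number of patients with at least one significant change anywhere."""
    return sum(
        1 for recs in records_by_patient.values() if any(r.significant for r in recs)
    )


def exclusion_report(studies: list[SpineStudy]) -> list[dict]:
    """Patients with any unmeasurable endplate, with level and reason.

    An endplate left unmeasurable means its symmetry profile was
    ambiguous with no prior to resolve it; the patient is excluded from
    all cohort summaries.
    """
    out = []
    for study in studies:
        bad = study.has_unmeasurable()
        if bad:
            out.append(
                {
                    "patient": study.patient,
                    "endplates": [f"{lvl} {side} @ {tp}" for (lvl, side, tp) in sorted(bad)],
                    "reason": "unresolvable ambiguity",
                }
            )
    return out


def summarize_cohort(
    studies: list[SpineStudy],
    limit: float,
    t1: str = "6m",
    t2: str = "24m",
) -> CohortSummary:
    """Full cohort pipeline: exclusions, gated records, matrix, junctions, counts."""
    exclusions = exclusion_report(studies)
    excluded = {e["patient"] for e in exclusions}
    included = [s for s in studies if s.patient not in excluded]
    records_by_patient = {
        s.patient: study_change_records(s, t1, t2, limit) for s in included
    }
    all_records = [r for recs in records_by_patient.values() for r in recs]
    build_change_matrix(all_records)  # validates duplicates
    junctions, detected, direction, notes = junction_summary(
        included, records_by_patient, limit
    )
    return CohortSummary(
        n_patients=len(included),
        n_excluded=len(excluded),
        exclusions=exclusions + notes,
        patients_with_significant_change=count_patients_with_change(records_by_patient),
        junction_means=junctions,
        en_bloc_detected=detected,
        en_bloc_direction=direction,
        records=records_to_frame(all_records),
    )
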
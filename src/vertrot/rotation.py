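"""Inter- and intra-vertebral rotation calculus.

Per-endplate axial angles (clockwise-positive viewed from above,
relative to the scanner-bed anteroposterior reference) are combined into:

* **intra-vertebral rotation** — superior minus inferior endplate of one
  vertebra (rotational deformity within the vertebra);
* **inter-vertebral (intra-discal) rotation** — inferior endplate of the
  cephalad vertebra minus superior endplate of the adjacent caudal
  vertebra.

Both are the signed minimal difference on the 180-degree axial circle,
mapped to (-90, +90].  Changes between two timepoints are t2 - t1.
Relative to the curve apex, negative changes above the apex and positive
changes below it increase the deformity, i.e. indicate loss of surgical
correction; a change is significant when its magnitude exceeds the
intra-observer 95% limit of agreement supplied by the reliability module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .errors import ParameterError
from .geometry import signed_axial_difference
from .symmetry import EndplateRotation

__all__ = [
    "SpineStudy",
    "RotationChangeRecord",
    "vertebra_sequence",
    "disc_key",
    "inter_endplate_rotation",
    "intra_vertebral_rotation",
    "inter_vertebral_rotation",
    "rotation_change",
    "classify_change",
    "direction_vs_apex",
    "study_change_records",
]

# Cephalad-to-caudal anatomical ordering used for level keys.
LEVEL_ORDER = (
    [f"C{i}" for i in range(1, 8)]
    + [f"T{i}" for i in range(1, 13)]
    + [f"L{i}" for i in range(1, 6)]
    + ["S1"]
)
_LEVEL_INDEX = {lvl: i for i, lvl in enumerate(LEVEL_ORDER)}


def vertebra_sequence(first: str, last: str) -> list[str]:
    """Anatomical vertebra labels from ``first`` to ``last`` inclusive, cephalad first."""
    try:
        i, j = _LEVEL_INDEX[first], _LEVEL_INDEX[last]
    except KeyError as e:  # pragma: no cover - defensive
        raise ParameterError(f"unknown vertebral level {e}") from e
    if i > j:
        raise ParameterError("first level must be cephalad of last")
    return LEVEL_ORDER[i : j + 1]


def disc_key(upper: str, lower: str) -> str:
    """Key of the disc between two adjacent vertebrae, e.g. ``T8/T9``."""
    return f"{upper}/{lower}"


@dataclass
class SpineStudy:
    """One patient's endplate rotations across levels and timepoints.

    ``levels`` runs cephalad to caudal and includes exactly one
    un-instrumented vertebra above and one below ``instrumented_range``
    (the scanned window).  ``apex`` names a vertebra (``T9``) or a disc
    (``T8/T9``) inside the instrumented range.
    """

    patient: str
    levels: list[str]
    instrumented_range: tuple[str, str]
    apex: str
    rotations: dict[tuple[str, str, str], EndplateRotation] = field(default_factory=dict)

    def __post_init__(self):
        top, bottom = self.instrumented_range
        if top not in self.levels or bottom not in self.levels:
            raise ParameterError("instrumented_range must lie within levels")
        it, ib = self.levels.index(top), self.levels.index(bottom)
        if it > ib:
            raise ParameterError("instrumented_range must be ordered cephalad, caudal")
        if it != 1 or ib != len(self.levels) - 2:
            raise ParameterError(
                "exactly one un-instrumented level is expected above and below the construct"
            )
        if self.apex not in self.entity_sequence():
            raise ParameterError("apex must name a vertebra or disc within the study")
        a0 = self.apex.split("/")[0]
        ia = self.levels.index(a0)
        if not (it <= ia <= ib):
            raise ParameterError("apex must lie within the instrumented range")

    # -- bookkeeping -------------------------------------------------------

    def endplate_sequence(self) -> list[tuple[str, str]]:
        """(level, side) pairs cephalad to caudal: sup/inf per vertebra."""
        out = []
        for lvl in self.levels:
            out.append((lvl, "superior"))
            out.append((lvl, "inferior"))
        return out

    def entity_sequence(self) -> list[str]:
        """Intra-vertebral and disc entity keys, cephalad to caudal.

        Each entity corresponds to one consecutive endplate pair:
        ``T5`` (within T5), ``T5/T6`` (disc), ``T6``, ...
        """
        out = []
        for k, lvl in enumerate(self.levels):
            out.append(lvl)
            if k + 1 < len(self.levels):
                out.append(disc_key(lvl, self.levels[k + 1]))
        return out

    def entity_kind(self, key: str) -> str:
        return "inter_vertebral" if "/" in key else "intra_vertebral"

    def is_instrumented(self, key: str) -> bool:
        """Whether an entity lies within the fused construct (inclusive of its endplates)."""
        top, bottom = self.instrumented_range
        it, ib = self.levels.index(top), self.levels.index(bottom)
        parts = key.split("/")
        idx = [self.levels.index(p) for p in parts]
        return all(it <= i <= ib for i in idx)

    def get_phi(self, level: str, side: str, timepoint: str) -> Optional[float]:
        rot = self.rotations.get((level, side, timepoint))
        if rot is None or rot.quality == "unmeasurable":
            return None
        return rot.phi

    def has_unmeasurable(self) -> list[tuple[str, str, str]]:
        return [k for k, r in self.rotations.items() if r.quality == "unmeasurable"]


@dataclass
class RotationChangeRecord:
    """One entity's rotation at two timepoints and its classified change."""

    patient: str
    level_key: str
    kind: str  # "inter_vertebral" | "intra_vertebral"
    value_t1: float
    value_t2: float
    change: float
    significant: bool
    direction_vs_apex: str  # "above" | "below" | "at"
    loss_of_correction: Optional[bool]  # None at the apex
    instrumented: bool = False


def inter_endplate_rotation(phi_upper: Optional[float], phi_lower: Optional[float]) -> float:
    """Signed rotation of the upper endplate relative to the lower, in (-90, +90].

    Positive = clockwise rotation of the cephalad endplate viewed from
    above.  Differences wrap on the 180-degree axial circle, so angles of
    1 and 179 degrees differ by +2, not -178.  Missing (unmeasurable)
    inputs propagate as NaN.
    """
    if phi_upper is None or phi_lower is None:
        return math.nan
    for p in (phi_upper, phi_lower):
        if not (0.0 <= p < 180.0):
            raise ParameterError("endplate angles must be in [0, 180)")
    return signed_axial_difference(phi_upper, phi_lower)


def intra_vertebral_rotation(study: SpineStudy, level: str, timepoint: str) -> float:
    """Rotation within one vertebra: superior endplate over inferior endplate."""
    return inter_endplate_rotation(
        study.get_phi(level, "superior", timepoint),
        study.get_phi(level, "inferior", timepoint),
    )


def inter_vertebral_rotation(
    study: SpineStudy, disc_between: tuple[str, str], timepoint: str
) -> float:
    """Intra-discal rotation: cephalad vertebra's inferior endplate over caudal's superior."""
    upper, lower = disc_between
    iu, il = study.levels.index(upper), study.levels.index(lower)
    if il != iu + 1:
        raise ParameterError("disc_between must name adjacent levels, cephalad first")
    return inter_endplate_rotation(
        study.get_phi(upper, "inferior", timepoint),
        study.get_phi(lower, "superior", timepoint),
    )


def rotation_change(value_t1: float, value_t2: float) -> float:
    """Change in an inter/intra-vertebral rotation between timepoints: t2 - t1."""
    return value_t2 - value_t1


def classify_change(
    change: float, direction_vs_apex: str, limit: float
) -> tuple[bool, Optional[bool]]:
    """Significance and loss-of-correction flags for one change.

    ``significant`` requires |change| strictly greater than ``limit``
    (the intra-observer 95% limit of agreement).  ``loss_of_correction``
    is True for negative changes above the apex or positive changes
    below it (the deformity-increasing directions); at the apex the flag
    is left unset (None).
    """
    if limit <= 0:
        raise ParameterError("limit must be positive")
    if math.isnan(change):
        return False, None
    significant = abs(change) > limit
    if direction_vs_apex == "at":
        return significant, None
    if direction_vs_apex not in ("above", "below"):
        raise ParameterError("direction_vs_apex must be above, below or at")
    loss = (change < 0 and direction_vs_apex == "above") or (
        change > 0 and direction_vs_apex == "below"
    )
    return significant, loss


def direction_vs_apex(study: SpineStudy, level_key: str) -> str:
    """Position of an entity relative to the study's curve apex."""
    seq = study.entity_sequence()
    i, a = seq.index(level_key), seq.index(study.apex)
    return "at" if i == a else ("above" if i < a else "below")


def study_change_records(
    study: SpineStudy, t1: str, t2: str, limit: float
) -> list[RotationChangeRecord]:
    """All measurable inter/intra-vertebral change records of one study.

    Entities with an unmeasurable endplate at either timepoint are
    omitted (missing propagates as missing, never as zero).
    """
    records = []
    for key in study.entity_sequence():
        kind = study.entity_kind(key)
        if kind == "intra_vertebral":
            v1 = intra_vertebral_rotation(study, key, t1)
            v2 = intra_vertebral_rotation(study, key, t2)
        else:
            pair = tuple(key.split("/"))
            v1 = inter_vertebral_rotation(study, pair, t1)
            v2 = inter_vertebral_rotation(study, pair, t2)
        if math.isnan(v1) or math.isnan(v2):
            continue
        change = rotation_change(v1, v2)
        direction = direction_vs_apex(study, key)
        significant, loss = classify_change(change, direction, limit)
        records.append(
            RotationChangeRecord(
                patient=study.patient,
                level_key=key,
                kind=kind,
                value_t1=v1,
                value_t2=v2,
                change=change,
                significant=significant,
                direction_vs_apex=direction,
                loss_of_correction=loss,
                instrumented=study.is_instrumented(key),
            )
        )
    return records
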
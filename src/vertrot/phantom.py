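"""Synthetic endplate phantoms, spine studies and observer-repeat pairs.

Everything downstream of the tracing step can be exercised against known
ground truth: endplate-like cross-sections with a controllable symmetry
axis, whole spine studies at two post-operative timepoints with injected
inter/intra-vertebral rotation changes, paired repeat measurements with
a stated noise SD, and small voxelized vertebra solids with tilted
endplate planes for the reformat pipeline.

The cross-section model is a superellipse body (lateral semi-axis
``body_width/2``, AP semi-axis ``body_depth/2``) with a smoothly
modulated posterior flattening and two posterior pedicle lobes raised as
radial bumps.  With the flattening and pedicles off the shape has two
perpendicular reflection axes (the ambiguous, near-elliptical case);
with either on, the anteroposterior axis is the unique axis of maximum
symmetry.  The canonical shape is built with its symmetry axis along the
AP reference and rotated clockwise by the requested ground-truth angle,
so rotation equivariance holds by construction to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import Polygon

from .errors import ParameterError, ResolutionError
from .geometry import cw_rotation_matrix, wrap_axial
from .reformat import EndplatePlane
from .rotation import SpineStudy, disc_key, vertebra_sequence
from .symmetry import EndplateOutline, EndplateRotation

__all__ = [
    "ShapeParams",
    "SyntheticSpineSpec",
    "RaterPairSpec",
    "TiltedVolume",
    "CohortTruth",
    "generate_endplate_outline",
    "generate_spine_study",
    "generate_rater_pairs",
    "generate_tilted_volume",
    "generate_cohort",
    "en_bloc_changes",
]


@dataclass(frozen=True)
class ShapeParams:
    """Parameters of the endplate cross-section model (lengths in mm).

    ``asymmetry_strength`` scales the posterior flattening that breaks
    the minor-axis symmetry; at 0 with no pedicles the shape degenerates
    to a superellipse with two reflection axes (used for ambiguity
    tests).  ``body_exponent`` 2 gives a true ellipse.
    """

    body_width: float = 40.0
    body_depth: float = 26.0
    posterior_flattening: float = 0.25
    pedicle_present: bool = True
    pedicle_length: float = 8.0
    pedicle_width: float = 9.0
    asymmetry_strength: float = 1.0
    body_exponent: float = 2.5

    def validate(self) -> None:
        if self.body_width <= 0 or self.body_depth <= 0:
            raise ParameterError("body dimensions must be positive")
        if not (0.0 <= self.posterior_flattening <= 1.0):
            raise ParameterError("posterior_flattening must be in [0, 1]")
        if self.asymmetry_strength < 0:
            raise ParameterError("asymmetry_strength must be >= 0")
        if self.pedicle_present and (self.pedicle_length <= 0 or self.pedicle_width <= 0):
            raise ParameterError("pedicle dimensions must be positive when pedicle_present")
        if self.body_exponent < 1.5:
            raise ParameterError("body_exponent must be >= 1.5")


def _canonical_radius(params: ShapeParams, psi: np.ndarray) -> np.ndarray:
    """Boundary radius r(psi) of the canonical shape (symmetry axis = +y).

    Even in psi about the y-axis (r(psi) == r(pi - psi)), which makes the
    sampled polygon exactly mirror-symmetric on a symmetric angle grid.
    """
    a = params.body_width / 2.0
    b = params.body_depth / 2.0
    p = params.body_exponent
    r = (np.abs(np.cos(psi) / a) ** p + np.abs(np.sin(psi) / b) ** p) ** (-1.0 / p)
    f = min(params.posterior_flattening * params.asymmetry_strength, 0.8)
    if f > 0:
        r = r * (1.0 - f * np.maximum(0.0, -np.sin(psi)) ** 2)
    if params.pedicle_present:
        r_post = float(
            (np.abs(np.cos(-np.pi / 2) / a) ** p + np.abs(np.sin(-np.pi / 2) / b) ** p)
            ** (-1.0 / p)
        )
        sigma = np.arctan2(params.pedicle_width / 2.0, r_post)
        for centre in (-np.pi / 2 - 0.7, -np.pi / 2 + 0.7):
            d = np.angle(np.exp(1j * (psi - centre)))
            r = r + params.pedicle_length * np.exp(-0.5 * (d / sigma) ** 2)
    return r


def generate_endplate_outline(
    params: ShapeParams,
    true_angle: float,
    centroid: Sequence[float] = (0.0, 0.0),
    seed: int = 0,
    noise_sd_mm: float = 0.0,
    n_vertices: int = 256,
    level: str = "",
    side: str = "",
    timepoint: str = "",
    patient: str = "",
) -> EndplateOutline:
    """Closed polygon phantom whose maximum-symmetry axis lies at ``true_angle``.

    Tracing noise is an independent radial Gaussian perturbation of each
    vertex (SD in mm), applied in the canonical frame so that identical
    seeds keep the construction exactly rotation-equivariant.
    """
    params.validate()
    if not (0.0 <= true_angle < 180.0):
        raise ParameterError("true_angle must be in [0, 180)")
    if noise_sd_mm < 0:
        raise ParameterError("noise_sd_mm must be >= 0")
    if n_vertices < 16 or n_vertices % 2:
        raise ParameterError("n_vertices must be an even number >= 16")
    psi = np.arange(n_vertices) * (2.0 * np.pi / n_vertices)
    r = _canonical_radius(params, psi)
    if noise_sd_mm > 0:
        rng = np.random.default_rng(seed)
        r = np.maximum(r + rng.normal(0.0, noise_sd_mm, n_vertices), 0.1)
    verts = np.column_stack([r * np.cos(psi), r * np.sin(psi)])
    verts = verts @ cw_rotation_matrix(true_angle).T + np.asarray(centroid, dtype=float)
    return EndplateOutline(
        verts,
        level=level,
        side=side,
        timepoint=timepoint,
        patient=patient,
        true_angle_deg=float(true_angle),
    )


# ---------------------------------------------------------------------------
# Spine studies with injected changes
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpineSpec:
    """Recipe for one patient's two-timepoint spine study.

    ``levels`` runs cephalad to caudal and includes the un-instrumented
    adjacent vertebra at each end; ``truth_angles_t1`` lists per-endplate
    angles in the endplate order (sup, inf per level); if omitted they
    are drawn near 90 degrees (anterior-facing spine on the scanner
    bed).  ``injected_changes`` maps entity keys (vertebra ``T8`` or
    disc ``T8/T9``) to the signed change (degrees) applied between the
    two timepoints; all other entities change by exactly zero.
    ``tracing_noise_mm`` is the radial SD of manual-tracing noise on
    generated outlines.
    """

    levels: list[str]
    instrumented_range: tuple[str, str]
    apex: str
    truth_angles_t1: Optional[Sequence[float]] = None
    injected_changes: dict = field(default_factory=dict)
    tracing_noise_mm: float = 0.0
    seed: int = 0
    patient: str = "P01"
    shape: ShapeParams = field(default_factory=ShapeParams)

    def validate(self) -> None:
        if len(self.levels) < 3:
            raise ParameterError("a study needs at least 3 levels")
        if self.truth_angles_t1 is not None:
            angles = np.asarray(self.truth_angles_t1, dtype=float)
            if angles.size != 2 * len(self.levels):
                raise ParameterError("truth_angles_t1 must list two angles per level")
            if np.any(angles < 0) or np.any(angles >= 180):
                raise ParameterError("truth angles must be in [0, 180)")
        if self.tracing_noise_mm < 0:
            raise ParameterError("tracing_noise_mm must be >= 0")


def en_bloc_changes(levels: list[str], instrumented_range: tuple[str, str], delta: float) -> dict:
    """Injected changes that rotate the whole fused construct by ``delta``.

    Rigid en-bloc rotation of every instrumented endplate shows up as a
    change of ``-delta`` at the superior junction disc, ``+delta`` at the
    inferior junction disc and zero at every within-construct entity.
    """
    top, bottom = instrumented_range
    it, ib = levels.index(top), levels.index(bottom)
    return {
        disc_key(levels[it - 1], top): -delta,
        disc_key(bottom, levels[ib + 1]): +delta,
    }


def generate_spine_study(
    spec: SyntheticSpineSpec,
    timepoints: tuple[str, str] = ("6m", "24m"),
    include_outlines: bool = False,
):
    """Build a :class:`SpineStudy` plus its ground-truth table.

    Per-endplate t2 angles are constructed by cumulative summation from
    the most caudal endplate so that each entity's inter-endplate change
    equals exactly its injected value and every other entity changes by
    zero.  Returns ``(study, truth_df)`` or ``(study, truth_df,
    outlines)`` with ``outlines[(level, side, timepoint)]``.
    """
    spec.validate()
    t1, t2 = timepoints
    study_probe = SpineStudy(
        patient=spec.patient,
        levels=list(spec.levels),
        instrumented_range=spec.instrumented_range,
        apex=spec.apex,
    )
    endplates = study_probe.endplate_sequence()
    entities = study_probe.entity_sequence()
    for key in spec.injected_changes:
        if key not in entities:
            raise ParameterError(f"injected change at unknown entity {key!r}")

    rng = np.random.default_rng(spec.seed)
    if spec.truth_angles_t1 is None:
        angles_t1 = wrap_axial(90.0 + rng.normal(0.0, 6.0) + np.cumsum(rng.normal(0, 1.5, len(endplates))))
    else:
        angles_t1 = np.asarray(spec.truth_angles_t1, dtype=float)

    # entity k sits between endplates k and k+1; change = delta_upper - delta_lower
    d = np.array([spec.injected_changes.get(k, 0.0) for k in entities])
    deltas = np.zeros(len(endplates))
    for j in range(len(endplates) - 2, -1, -1):
        deltas[j] = deltas[j + 1] + d[j]
    angles_t2 = wrap_axial(angles_t1 + deltas)

    rows = []
    for (lvl, side), a1, a2 in zip(endplates, angles_t1, angles_t2):
        for tp, ang in ((t1, a1), (t2, a2)):
            rows.append(
                {"patient": spec.patient, "level": lvl, "side": side,
                 "timepoint": tp, "true_angle_deg": float(ang)}
            )
            study_probe.rotations[(lvl, side, tp)] = EndplateRotation(
                phi=float(ang), level=lvl, side=side, timepoint=tp,
                patient=spec.patient, quality="ok",
            )
    truth = pd.DataFrame(rows)

    if not include_outlines:
        return study_probe, truth

    outlines = {}
    for k, ((lvl, side), a1, a2) in enumerate(zip(endplates, angles_t1, angles_t2)):
        for tp, ang in ((t1, a1), (t2, a2)):
            outlines[(lvl, side, tp)] = generate_endplate_outline(
                spec.shape, float(ang), seed=int(spec.seed * 10007 + k),
                noise_sd_mm=spec.tracing_noise_mm,
                level=lvl, side=side, timepoint=tp, patient=spec.patient,
            )
    return study_probe, truth, outlines


# ---------------------------------------------------------------------------
# Observer repeat pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RaterPairSpec:
    """Repeated-measurement simulation: two reads of each change value.

    ``measurement_noise_sd`` is the per-read Gaussian noise SD in
    degrees, emulating the manual reformat + tracing variability of a
    single observer re-measuring after an interval.
    """

    n_pairs: int
    measurement_noise_sd: float
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ParameterError("n_pairs must be >= 2")
        if self.measurement_noise_sd < 0:
            raise ParameterError("measurement_noise_sd must be >= 0")


def generate_rater_pairs(spec: RaterPairSpec, base_changes: Sequence[float]) -> pd.DataFrame:
    """Two independent noisy replicates of each base change value.

    Returns a DataFrame with columns ``level_key, alpha_n, alpha_m``;
    identical spec and seed reproduce the table exactly.
    """
    spec.validate()
    base = np.asarray(base_changes, dtype=float)
    if base.size != spec.n_pairs:
        raise ParameterError("n_pairs must match the number of base changes")
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.measurement_noise_sd, size=(2, base.size))
    return pd.DataFrame(
        {
            "level_key": [f"pair{i:05d}" for i in range(base.size)],
            "alpha_n": base + noise[0],
            "alpha_m": base + noise[1],
        }
    )


# ---------------------------------------------------------------------------
# Tilted 3D phantoms
# ---------------------------------------------------------------------------


@dataclass
class TiltedVolume:
    """A voxelized vertebra-like prism with a tilted endplate plane."""

    volume: np.ndarray  # float32 fractional occupancy in [0, 1], indexed [ix, iy, iz]
    voxel_spacing: np.ndarray  # (3,) mm
    origin: np.ndarray  # (3,) mm, world coords of voxel (0,0,0) centre
    landmarks: np.ndarray  # (k, 3) points on the endplate plane
    plane: EndplatePlane  # analytic ground-truth plane
    true_angle: float


def generate_tilted_volume(
    params: ShapeParams,
    true_angle: float,
    tilt: tuple[float, float] = (0.0, 0.0),
    voxel_size: float = 1.0,
    thickness: float = 18.0,
    n_landmarks: int = 6,
    margin: float = 4.0,
) -> TiltedVolume:
    """Voxelize a vertebra-like solid whose endplate plane has the given tilt.

    ``tilt`` = (frontal, sagittal) rotations in degrees applied to the
    endplate normal (|each| < 45).  The solid is the endplate
    cross-section at in-plane rotation ``true_angle`` extruded caudally
    by ``thickness`` below the endplate plane, voxelized as fractional
    occupancy (partial-volume) values; landmark points lie exactly on
    the plane.
    """
    params.validate()
    tx, ty = tilt
    if max(abs(tx), abs(ty)) >= 45.0:
        raise ParameterError("tilt components must satisfy |t| < 45 degrees")
    if min(params.body_width, params.body_depth) / voxel_size < 10:
        raise ResolutionError("voxel_size too coarse to resolve the endplate shape")

    ax, ay = np.deg2rad(tx), np.deg2rad(ty)
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    n = ry @ rx @ np.array([0.0, 0.0, 1.0])
    ap = np.array([0.0, 1.0, 0.0])
    y0 = ap - (ap @ n) * n
    y0 /= np.linalg.norm(y0)
    x0 = np.cross(y0, n)
    plane = EndplatePlane(np.zeros(3), n, y0)

    outline = generate_endplate_outline(params, true_angle)
    poly = Polygon(outline.vertices)
    r_xy = float(np.max(np.linalg.norm(outline.vertices, axis=1))) + margin

    # world-space bounding box of the tilted prism
    corners = []
    for sx in (-r_xy, r_xy):
        for sy in (-r_xy, r_xy):
            for sz in (-thickness - margin, margin):
                corners.append(sx * x0 + sy * y0 + sz * n)
    corners = np.array(corners)
    half = np.max(np.abs(corners), axis=0)
    shape = (np.ceil(2 * half / voxel_size)).astype(int) + 1
    origin = -(shape - 1) / 2.0 * voxel_size

    axes = [origin[k] + np.arange(shape[k]) * voxel_size for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    zeta = pts @ n
    # candidate voxels: within half a voxel diagonal of the prism slab
    pad = 0.87 * voxel_size
    band = (zeta <= pad) & (zeta >= -thickness - pad)
    vol = np.zeros(tuple(shape), dtype=np.float32)
    if band.any():
        # fractional occupancy by 3x3x3 subvoxel sampling: emulates the
        # partial-volume effect and avoids the binary staircase, whose
        # mirror-consistency about the grid axes biases the symmetry peak
        sub = pts[band]
        occ = np.zeros(len(sub))
        offs = (np.arange(3) - 1.0) / 3.0 * voxel_size
        for dx in offs:
            for dy in offs:
                for dz in offs:
                    q = sub + np.array([dx, dy, dz])
                    z = q @ n
                    inside = (z <= 0.0) & (z >= -thickness)
                    if inside.any():
                        qi = q[inside]
                        inside[inside.copy()] = contains_xy(poly, qi @ x0, qi @ y0)
                        occ += inside
        vol[band] = occ / 27.0

    r_l = 0.3 * min(params.body_width, params.body_depth) / 2.0 * 2.0
    psi = np.arange(n_landmarks) * (2 * np.pi / n_landmarks)
    landmarks = (r_l * np.cos(psi))[:, None] * x0 + (r_l * np.sin(psi))[:, None] * y0

    return TiltedVolume(
        volume=vol,
        voxel_spacing=np.full(3, float(voxel_size)),
        origin=origin.astype(float),
        landmarks=landmarks,
        plane=plane,
        true_angle=float(true_angle),
    )


# ---------------------------------------------------------------------------
# Whole cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortTruth:
    """A synthetic cohort with its injected-change ground truth."""

    studies: list[SpineStudy]
    injected: dict  # patient -> {entity_key: injected change, deg}
    truth_table: pd.DataFrame  # per-endplate true angles, long format

    @property
    def n_patients(self) -> int:
        return len(self.studies)


_PROXIMAL = ["T4"] * 2 + ["T5"] * 14 + ["T6"] * 14 + ["T7"] * 2
_DISTAL = ["T11"] * 5 + ["T12"] * 21 + ["L1"] * 6


def generate_cohort(
    n_patients: int = 32,
    n_with_significant: int = 11,
    seed: int = 0,
    significant_range: tuple[float, float] = (9.0, 13.0),
    minor_magnitude_max: float = 4.0,
    timepoints: tuple[str, str] = ("6m", "24m"),
) -> CohortTruth:
    """Generate a cohort emulating an instrumented thoracic fusion series.

    Instrumented ranges follow the reported distribution of proximal
    (T4:2, T5:14, T6:14, T7:2) and distal (T11:5, T12:21, L1:6) levels
    for a 32-patient cohort; the curve apex sits mid-construct.  Exactly
    ``n_with_significant`` patients receive one injected change whose
    magnitude exceeds the 8.2-degree gate; the remainder receive only
    sub-gate changes, so downstream counting has a known answer.
    """
    if not (0 <= n_with_significant <= n_patients):
        raise ParameterError("n_with_significant must be within [0, n_patients]")
    rng = np.random.default_rng(seed)
    proximal = [ _PROXIMAL[rng.integers(len(_PROXIMAL))] for _ in range(n_patients)]
    distal = [_DISTAL[rng.integers(len(_DISTAL))] for _ in range(n_patients)]

    significant_flags = np.zeros(n_patients, dtype=bool)
    significant_flags[:n_with_significant] = True
    rng.shuffle(significant_flags)

    studies, injected = [], {}
    rows = []
    for i in range(n_patients):
        pid = f"P{i + 1:02d}"
        top, bottom = proximal[i], distal[i]
        span = vertebra_sequence(top, bottom)
        while not (6 <= len(span) <= 9):  # match the reported 6-9 instrumented levels
            top = _PROXIMAL[rng.integers(len(_PROXIMAL))]
            bottom = _DISTAL[rng.integers(len(_DISTAL))]
            span = vertebra_sequence(top, bottom)
        levels = vertebra_sequence(
            vertebra_sequence("T1", top)[-2], vertebra_sequence(bottom, "L5")[1]
        )
        probe = SpineStudy(pid, levels, (top, bottom), apex=span[len(span) // 2])
        entities = probe.entity_sequence()
        apex_pool = [k for k in entities if probe.is_instrumented(k)]
        apex = apex_pool[len(apex_pool) // 2 + int(rng.integers(-1, 2))]

        instrumented = [k for k in entities if probe.is_instrumented(k)]
        changes: dict[str, float] = {}
        if significant_flags[i]:
            key = instrumented[int(rng.integers(len(instrumented)))]
            mag = float(rng.uniform(*significant_range))
            changes[key] = mag * (1 if rng.random() < 0.5 else -1)
        for _ in range(int(rng.integers(0, 3))):
            key = instrumented[int(rng.integers(len(instrumented)))]
            if key in changes:
                continue
            changes[key] = float(rng.uniform(-minor_magnitude_max, minor_magnitude_max))

        spec = SyntheticSpineSpec(
            levels=levels,
            instrumented_range=(top, bottom),
            apex=apex,
            injected_changes=changes,
            seed=int(rng.integers(2**31 - 1)),
            patient=pid,
        )
        study, truth = generate_spine_study(spec, timepoints=timepoints)
        studies.append(study)
        injected[pid] = changes
        rows.append(truth)

    return CohortTruth(studies=studies, injected=injected, truth_table=pd.concat(rows, ignore_index=True))
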
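"""Serialization: outlines as JSON, masks as PNG/TIFF with sidecars, volumes as NIfTI, tables as CSV."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .reliability import ReliabilityResult
from .rotation import RotationChangeRecord
from .symmetry import BinaryEndplateImage, EndplateOutline, EndplateRotation, SymmetryProfile
from .cohort import records_to_frame

__all__ = [
    "outline_to_json", "outline_from_json", "save_outline", "load_outline",
    "save_mask", "load_mask", "save_volume_nifti", "load_volume_nifti",
    "rotations_to_frame", "save_rotations_csv", "load_rotations_csv",
    "save_change_records_csv", "load_change_records_csv",
    "save_profile_csv", "reliability_to_json",
]


# -- outlines ---------------------------------------------------------------


def outline_to_json(outline: EndplateOutline) -> str:
    payload = {
        "vertices_mm": np.asarray(outline.vertices, float).tolist(),
        "level": outline.level,
        "side": outline.side,
        "timepoint": outline.timepoint,
        "patient": outline.patient,
        "true_angle_deg": outline.true_angle_deg,
    }
    return json.dumps(payload, indent=2)


def outline_from_json(text: str) -> EndplateOutline:
    d = json.loads(text)
    return EndplateOutline(
        vertices=np.asarray(d["vertices_mm"], dtype=float),
        level=d.get("level", ""),
        side=d.get("side", ""),
        timepoint=d.get("timepoint", ""),
        patient=d.get("patient", ""),
        true_angle_deg=d.get("true_angle_deg"),
    )


def save_outline(outline: EndplateOutline, path: str | Path) -> None:
    Path(path).write_text(outline_to_json(outline))


def load_outline(path: str | Path) -> EndplateOutline:
    return outline_from_json(Path(path).read_text())


# -- binary masks -----------------------------------------------------------


def save_mask(image: BinaryEndplateImage, path: str | Path) -> None:
    """Write a mask as PNG/TIFF plus a JSON sidecar with spacing and origin."""
    path = Path(path)
    iio.imwrite(path, (image.mask.astype(np.uint8) * 255))
    sidecar = {
        "pixel_spacing_mm": image.pixel_spacing,
        "origin_mm": [float(image.origin[0]), float(image.origin[1])],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_mask(path: str | Path) -> BinaryEndplateImage:
    path = Path(path)
    mask = np.asarray(iio.imread(path)) > 127
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return BinaryEndplateImage(
        mask, sidecar["pixel_spacing_mm"], origin=tuple(sidecar["origin_mm"])
    )


# -- volumes ----------------------------------------------------------------


def save_volume_nifti(
    volume: np.ndarray, voxel_spacing, origin, path: str | Path
) -> None:
    affine = np.diag(list(np.asarray(voxel_spacing, float)) + [1.0])
    affine[:3, 3] = np.asarray(origin, float)
    nib.save(nib.Nifti1Image(np.asarray(volume), affine), str(path))


def load_volume_nifti(path: str | Path):
    img = nib.load(str(path))
    affine = img.affine
    return (
        np.asarray(img.dataobj),
        np.diag(affine)[:3].copy(),
        affine[:3, 3].copy(),
    )


# -- tables -----------------------------------------------------------------


def rotations_to_frame(rotations: Iterable[EndplateRotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"patient": r.patient, "level": r.level, "side": r.side,
             "timepoint": r.timepoint, "phi_deg": r.phi, "quality": r.quality}
            for r in rotations
        ],
        columns=["patient", "level", "side", "timepoint", "phi_deg", "quality"],
    )


def save_rotations_csv(rotations: Iterable[EndplateRotation], path: str | Path) -> None:
    rotations_to_frame(rotations).to_csv(path, index=False)


def load_rotations_csv(path: str | Path) -> list[EndplateRotation]:
    frame = pd.read_csv(path)
    out = []
    for row in frame.itertuples(index=False):
        phi = None if pd.isna(row.phi_deg) else float(row.phi_deg)
        out.append(
            EndplateRotation(phi=phi, level=str(row.level), side=str(row.side),
                             timepoint=str(row.timepoint), patient=str(row.patient),
                             quality=str(row.quality))
        )
    return out


def save_change_records_csv(records: Iterable[RotationChangeRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def load_change_records_csv(path: str | Path) -> list[RotationChangeRecord]:
    frame = pd.read_csv(path)
    out = []
    for row in frame.itertuples(index=False):
        loss = row.loss_of_correction
        out.append(
            RotationChangeRecord(
                patient=str(row.patient), level_key=str(row.level_key), kind=str(row.kind),
                value_t1=float(row.value_t1), value_t2=float(row.value_t2),
                change=float(row.change), significant=bool(row.significant),
                direction_vs_apex=str(row.direction_vs_apex),
                loss_of_correction=None if pd.isna(loss) else bool(loss),
                instrumented=bool(row.instrumented),
            )
        )
    return out


def save_profile_csv(profile: SymmetryProfile, path: str | Path) -> None:
    """Angle/ratio table for plotting the symmetry-ratio-vs-angle curve."""
    pd.DataFrame({"angle_deg": profile.angles, "ratio": profile.ratios}).to_csv(
        path, index=False
    )


def reliability_to_json(result: ReliabilityResult) -> str:
    return json.dumps(
        {"sd_intra": result.sd_intra, "loa95": result.loa95, "n_pairs": result.n_pairs},
        indent=2,
    )
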
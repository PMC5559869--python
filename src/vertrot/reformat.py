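"""True-axial reformatting: slicing a CT volume in the plane of an endplate.

A vertebral endplate is generally tilted relative to the scanner's axial
plane; angles must be measured on a *true axial* slice lying in the
endplate plane.  The plane is fitted to observer-placed landmark points,
its normal oriented cranially so every slice is emitted in
viewed-from-above orientation, and the scanner-bed anteroposterior axis
is projected into the plane to serve as the in-slice angular reference.
Carrying that reference makes in-plane angles comparable across
endplates and invariant to how the slice pixel grid happens to be
oriented.

Volumes are arrays indexed ``[ix, iy, iz]`` with world coordinates
``origin + index * spacing`` (mm); +z is cranial and +y anterior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import (
    EmptySliceError,
    GeometryError,
    ParameterError,
    ReferenceUndefinedError,
)
from .symmetry import BinaryEndplateImage

__all__ = ["EndplatePlane", "TrueAxialSlice", "fit_endplate_plane", "extract_true_axial"]

AP_AXIS = np.array([0.0, 1.0, 0.0])  # scanner-bed anteroposterior (anterior positive)
CRANIAL_AXIS = np.array([0.0, 0.0, 1.0])


@dataclass
class EndplatePlane:
    """An endplate plane with its in-plane angular reference.

    ``normal`` points cranially; ``in_plane_reference`` is the unit
    projection of the scanner AP axis onto the plane.  The two are
    orthogonal to within 1e-9.
    """

    origin: np.ndarray
    normal: np.ndarray
    in_plane_reference: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        self.in_plane_reference = np.asarray(self.in_plane_reference, dtype=float)
        for v in (self.normal, self.in_plane_reference):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ParameterError("plane vectors must be unit length")
        if abs(float(self.normal @ self.in_plane_reference)) > 1e-9:
            raise ParameterError("in_plane_reference must be orthogonal to the normal")


@dataclass
class TrueAxialSlice:
    """A resampled 2D slice in the endplate plane, viewed from above.

    ``data[i, j]`` sits at 2D plane coordinates ``origin + (j, i) * pixel_spacing``.
    ``reference`` is the in-plane AP reference expressed in the slice's
    2D coordinate frame; angles measured relative to it do not depend on
    the pixel-grid orientation.
    """

    data: np.ndarray
    pixel_spacing: float
    origin: tuple[float, float]
    reference: np.ndarray

    def to_binary_image(self, threshold: float = 0.5) -> BinaryEndplateImage:
        """Rebinarize an interpolated mask slice."""
        return BinaryEndplateImage(self.data > threshold, self.pixel_spacing, self.origin)


def fit_endplate_plane(
    landmarks: np.ndarray,
    ap_axis: Sequence[float] = AP_AXIS,
    cranial_axis: Sequence[float] = CRANIAL_AXIS,
) -> EndplatePlane:
    """Least-squares plane through >= 3 non-collinear landmark points (mm).

    The plane minimizes the sum of squared point-to-plane distances; its
    normal is oriented toward the cranial direction and the in-plane
    reference is the normalized projection of the scanner AP axis.
    """
    pts = np.asarray(landmarks, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ParameterError("landmarks must be an (n >= 3, 3) array of mm coordinates")
    c = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - c)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise GeometryError("landmarks are collinear; plane is undefined")
    n = vt[2]
    if float(n @ np.asarray(cranial_axis, float)) < 0:
        n = -n
    ap = np.asarray(ap_axis, dtype=float)
    ref = ap - (ap @ n) * n
    nrm = np.linalg.norm(ref)
    if nrm < 1e-9:
        raise ReferenceUndefinedError("AP axis is parallel to the plane normal")
    return EndplatePlane(c, n / np.linalg.norm(n), ref / nrm)


def _in_plane_axes(plane: EndplatePlane, grid_rotation_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed in-plane axes; pixel +y along the reference when rotation is 0."""
    y0 = plane.in_plane_reference
    x0 = np.cross(y0, plane.normal)
    x0 /= np.linalg.norm(x0)
    a = np.deg2rad(grid_rotation_deg)
    x_s = np.cos(a) * x0 + np.sin(a) * y0
    y_s = -np.sin(a) * x0 + np.cos(a) * y0
    return x_s, y_s


def extract_true_axial(
    volume: np.ndarray,
    voxel_spacing: Sequence[float],
    volume_origin: Sequence[float],
    plane: EndplatePlane,
    field_of_view: float,
    pixel_spacing: float,
    grid_rotation_deg: float = 0.0,
    offset_mm: float = 0.0,
    binarize: Optional[float] = None,
) -> TrueAxialSlice:
    """Resample the volume on the endplate plane (trilinear interpolation).

    ``offset_mm`` shifts the sampling plane along the (cranial) normal;
    a small negative offset samples just inside the endplate, away from
    the knife-edge top face of a binary phantom.  ``binarize`` applies a
    threshold (0.5 for mask phantoms) to the interpolated slice.
    Raises :class:`EmptySliceError` when the plane misses the volume.
    """
    vol = np.asarray(volume)
    sp = np.asarray(voxel_spacing, dtype=float)
    vo = np.asarray(volume_origin, dtype=float)
    if vol.ndim != 3:
        raise ParameterError("volume must be a 3D array")
    if pixel_spacing <= 0 or field_of_view <= 0:
        raise ParameterError("field_of_view and pixel_spacing must be positive")
    x_s, y_s = _in_plane_axes(plane, grid_rotation_deg)
    npix = int(round(field_of_view / pixel_spacing))
    off = (np.arange(npix) - (npix - 1) / 2.0) * pixel_spacing
    centre = plane.origin + offset_mm * plane.normal
    # world coords of every slice pixel centre: (npix, npix, 3)
    pts = centre + off[None, :, None] * x_s + off[:, None, None] * y_s
    idx = (pts - vo) / sp  # fractional voxel indices
    inside = np.all((idx >= -0.5) & (idx <= np.array(vol.shape) - 0.5), axis=-1)
    if not inside.any():
        raise EmptySliceError("the requested plane does not intersect the volume")
    coords = [idx[..., k].ravel() for k in range(3)]
    data = map_coordinates(
        vol.astype(np.float32), coords, order=1, mode="constant", cval=0.0
    ).reshape(npix, npix)
    if binarize is not None:
        data = data > binarize
    ref2d = np.array([float(plane.in_plane_reference @ x_s), float(plane.in_plane_reference @ y_s)])
    half = (npix - 1) / 2.0 * pixel_spacing
    return TrueAxialSlice(data, pixel_spacing, origin=(-half, -half), reference=ref2d)
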
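"""Angle conventions and small planar-geometry helpers.

Conventions used throughout the package
---------------------------------------
* True-axial slices are viewed from above (cranial side), with +x to the
  patient's left on screen and +y anterior.  The in-slice reference
  direction is the projection of the scanner-bed anteroposterior axis,
  ``(0, 1)`` by default.
* An endplate orientation ``phi`` is the *clockwise* angle (viewed from
  above) from the reference direction to the endplate's symmetry axis,
  in degrees in ``[0, 180)``.  Symmetry axes are undirected, hence the
  180-degree period.
* Signed differences between two axial angles live on the 180-degree
  circle and are mapped to ``(-90, +90]``; positive means the first
  angle is clockwise of the second.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "cw_rotation_matrix",
    "axis_direction",
    "wrap_axial",
    "signed_axial_difference",
    "axial_distance",
]


def cw_rotation_matrix(angle_deg: float) -> np.ndarray:
    """2x2 matrix rotating plane vectors clockwise (viewed from above) by ``angle_deg``."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, s], [-s, c]])


def axis_direction(phi_deg, reference=(0.0, 1.0)) -> np.ndarray:
    """Unit direction of the axis at clockwise angle ``phi_deg`` from ``reference``.

    ``phi_deg`` may be a scalar or array; the result has shape ``(..., 2)``.
    """
    ref = np.asarray(reference, dtype=float)
    ref = ref / np.linalg.norm(ref)
    a = np.deg2rad(np.asarray(phi_deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    # clockwise rotation of ref by phi
    return np.stack([c * ref[0] + s * ref[1], -s * ref[0] + c * ref[1]], axis=-1)


def wrap_axial(angle_deg):
    """Wrap an angle (scalar or array) into ``[0, 180)``."""
    return np.mod(angle_deg, 180.0)


def signed_axial_difference(a_deg: float, b_deg: float) -> float:
    """Minimal signed difference ``a - b`` on the 180-degree circle, in ``(-90, +90]``.

    Positive values mean ``a`` is clockwise of ``b`` viewed from above.
    """
    d = np.mod((a_deg - b_deg) + 90.0, 180.0) - 90.0
    if np.ndim(d) == 0:
        return float(90.0 if d == -90.0 else d)
    d = np.where(d == -90.0, 90.0, d)
    return d


def axial_distance(a_deg: float, b_deg: float) -> float:
    """Absolute circular distance between two axial angles, in ``[0, 90]``."""
    d = np.abs(np.mod(a_deg - b_deg, 180.0))
    return float(np.minimum(d, 180.0 - d)) if np.ndim(d) == 0 else np.minimum(d, 180.0 - d)
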
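"""Rotation conventions shared by the phantom and midplane modules.

The coronal angle is a rotation about the y (posterior-anterior) axis and
the transverse angle a rotation about the z (inferior-superior) axis, in the
package-wide (x, y, z) = (left-right, posterior-anterior, inferior-superior)
axis order.  The two single-plane rotations compose as
``R = R_z(transverse) @ R_y(coronal)``; for the small angles on the
classifier grid (|angle| <= 5 deg) the commutator of the two factors is far
below voxel scale, so the pinned order is a reproducibility choice, not a
modelling one.
"""

from __future__ import annotations

import numpy as np


def rot_y(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_matrix(coronal_deg: float, transverse_deg: float) -> np.ndarray:
    """Composed rigid rotation ``R_z(transverse) @ R_y(coronal)``."""
    return rot_z(transverse_deg) @ rot_y(coronal_deg)
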
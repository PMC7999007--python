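"""3D geometric moments and the volume centroid.

The (p+q+r)-th order geometric moment of a sampled image f(x, y, z) is

    M_pqr = sum_x sum_y sum_z  x^p y^q z^r f(x, y, z)

over 0-based voxel indices; M_000 is the image mass and the centroid is
(M_100 / M_000, M_010 / M_000, M_001 / M_000).  Moments are computed over
voxel indices (unitless, integer-exact for masks); world-mm conversion is a
separate step so the internal arithmetic stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import Volume

__all__ = ["MomentSet", "moment", "centroid", "centroid_world", "moment_set"]


@dataclass(frozen=True)
class MomentSet:
    m000: float
    m100: float
    m010: float
    m001: float
    centroid: tuple[float, float, float]


def moment(volume: Volume, p: int, q: int, r: int) -> float:
    """Geometric moment M_pqr of the volume's gray function."""
    if p < 0 or q < 0 or r < 0:
        raise ValueError(f"moment orders must be nonnegative, got ({p},{q},{r})")
    f = volume.data.astype(float)
    nx, ny, nz = f.shape
    xp = np.arange(nx, dtype=float) ** p
    yq = np.arange(ny, dtype=float) ** q
    zr = np.arange(nz, dtype=float) ** r
    return float(np.einsum("i,j,k,ijk->", xp, yq, zr, f))


def centroid(volume: Volume) -> tuple[float, float, float]:
    """Center of mass in voxel coordinates: first moments over the mass.

    Raises on an all-zero volume (zero mass) instead of returning NaN.
    """
    m000 = moment(volume, 0, 0, 0)
    if m000 == 0:
        raise ValueError("centroid undefined: volume has zero mass (M000 = 0)")
    return (
        moment(volume, 1, 0, 0) / m000,
        moment(volume, 0, 1, 0) / m000,
        moment(volume, 0, 0, 1) / m000,
    )


def centroid_world(volume: Volume) -> tuple[float, float, float]:
    """Centroid in world millimetres (origin + voxel centroid * spacing)."""
    c = centroid(volume)
    return tuple(
        float(o + ci * s) for o, ci, s in zip(volume.origin, c, volume.spacing)
    )


def moment_set(volume: Volume) -> MomentSet:
    """M000 and the three first-order moments plus the centroid."""
    m000 = moment(volume, 0, 0, 0)
    if m000 == 0:
        raise ValueError("volume has zero mass (M000 = 0)")
    m100 = moment(volume, 1, 0, 0)
    m010 = moment(volume, 0, 1, 0)
    m001 = moment(volume, 0, 0, 1)
    return MomentSet(
        m000, m100, m010, m001, (m100 / m000, m010 / m000, m001 / m000)
    )
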
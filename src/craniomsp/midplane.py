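"""Midsagittal-plane construction, alignment and symmetry scoring.

The detected rotation offsets and the moment centroid combine into the
bilateral symmetry midplane: the plane through the centroid whose normal is
the canonical sagittal normal (1, 0, 0) rotated forward by the detected
coronal and transverse angles.  A reflection-based Dice score quantifies
how well a candidate plane bisects a mask into mirror halves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._rotations import rotation_matrix, rot_y, rot_z
from .metrics import dice
from .volume_io import Volume, TriangleMesh, write_mesh

__all__ = [
    "PlaneSpec",
    "construct_plane",
    "align_volume",
    "plane_symmetry_score",
    "export_plane",
    "load_plane",
]


@dataclass(frozen=True)
class PlaneSpec:
    """A 3D plane as (point, unit normal) in world millimetres."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        if p.shape != (3,) or n.shape != (3,):
            raise ValueError("point and normal must be 3-vectors")
        if not (np.isfinite(p).all() and np.isfinite(n).all()):
            raise ValueError("plane point/normal must be finite")
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError(f"normal must be unit length, got |n|={np.linalg.norm(n)}")
        object.__setattr__(self, "point", tuple(float(v) for v in p))
        object.__setattr__(self, "normal", tuple(float(v) for v in n))

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - np.asarray(self.point)) @ np.asarray(self.normal)


def construct_plane(
    centroid_world, coronal_deg: float, transverse_deg: float
) -> PlaneSpec:
    """Midplane through the centroid with the rotated sagittal normal.

    normal = R_z(transverse) @ R_y(coronal) @ (1, 0, 0); at zero angles
    this is the exact voxel-grid sagittal plane x = centroid_x.
    """
    c = np.asarray(centroid_world, dtype=float)
    if not (np.isfinite(c).all()
            and np.isfinite([coronal_deg, transverse_deg]).all()):
        raise ValueError("centroid and angles must be finite")
    n = rotation_matrix(coronal_deg, transverse_deg) @ np.array([1.0, 0.0, 0.0])
    n /= np.linalg.norm(n)
    return PlaneSpec(tuple(c), tuple(n))


def align_volume(
    volume: Volume, coronal_deg: float, transverse_deg: float
) -> Volume:
    """Undo a detected rotation so the symmetry plane maps onto the grid's
    central sagittal plane.

    Applies the exact inverse of the forward rotation
    ``R_z(transverse) @ R_y(coronal)`` (i.e. the negated angles composed in
    reversed order), nearest-neighbor resampled.
    """
    if coronal_deg == 0.0 and transverse_deg == 0.0:
        return volume.copy_with(volume.data.copy())
    from scipy import ndimage

    R = rot_y(-coronal_deg) @ rot_z(-transverse_deg)  # inverse rotation
    center = (np.asarray(volume.shape) - 1) / 2
    M = R.T
    out = ndimage.affine_transform(
        volume.data, M, offset=center - M @ center, order=0,
        mode="constant", cval=0, output=volume.data.dtype,
    )
    return volume.copy_with(out)


def plane_symmetry_score(volume: Volume, plane: PlaneSpec) -> float:
    """Dice overlap between a mask and its reflection across the plane.

    1.0 means perfect bilateral symmetry about the plane (up to
    nearest-neighbor resampling loss); the score is invariant to the sign
    of the plane normal.
    """
    mask = volume.mask_array()
    if not mask.any():
        raise ValueError("symmetry score undefined for an empty mask")
    idx = np.argwhere(np.ones(volume.shape, dtype=bool))
    pts = volume.world_coords(idx)
    n = np.asarray(plane.normal)
    d = plane.signed_distance(pts)
    refl = pts - 2.0 * d[:, None] * n
    ridx = np.rint((refl - np.asarray(volume.origin)) / np.asarray(volume.spacing))
    ridx = ridx.astype(int)
    inside = np.all((ridx >= 0) & (ridx < np.asarray(volume.shape)), axis=1)
    reflected = np.zeros(volume.shape, dtype=np.uint8)
    flat_src = ridx[inside]
    reflected[tuple(idx[inside].T)] = mask[tuple(flat_src.T)]
    return dice(volume.copy_with(mask.astype(np.uint8)),
                volume.copy_with(reflected))


def _bbox_quad(plane: PlaneSpec, volume: Volume) -> np.ndarray:
    """Corners of a plane-inscribed quad clipped to the volume bounding box."""
    lo = np.asarray(volume.origin)
    hi = lo + (np.asarray(volume.shape) - 1) * np.asarray(volume.spacing)
    n = np.asarray(plane.normal)
    bc = (lo + hi) / 2
    center = bc - plane.signed_distance(bc)[0] * n
    if np.any(center < lo - 1e-9) or np.any(center > hi + 1e-9):
        center = np.clip(center, lo, hi)
        center = center - plane.signed_distance(center)[0] * n
    # in-plane orthonormal frame
    a = np.array([0.0, 0.0, 1.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    corners = []
    for du, dv in ((1, 1), (-1, 1), (-1, -1), (1, -1)):
        d = du * u + dv * v
        # max step t with center + t*d inside [lo, hi]
        with np.errstate(divide="ignore"):
            t_hi = np.where(d > 1e-12, (hi - center) / d, np.inf)
            t_lo = np.where(d < -1e-12, (lo - center) / d, np.inf)
        t = min(float(np.min(t_hi)), float(np.min(t_lo)))
        corners.append((d, max(t, 0.0)))
    s = min(t for _, t in corners)
    return np.array([center + s * d for d, _ in corners])


def export_plane(plane: PlaneSpec, volume: Volume, path) -> None:
    """Write the plane as a two-triangle STL patch plus a JSON sidecar.

    The patch is a quad inscribed in the plane and clipped to the volume's
    world bounding box; the sidecar (``<path>.json``) holds (point, normal)
    and round-trips via :func:`load_plane`.
    """
    path = Path(path)
    quad = _bbox_quad(plane, volume)
    mesh = TriangleMesh(quad, np.array([[0, 1, 2], [0, 2, 3]]))
    write_mesh(mesh, path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"point": list(plane.point), "normal": list(plane.normal)},
                   indent=2)
    )


def load_plane(path) -> PlaneSpec:
    """Read a plane back from the JSON sidecar written by export_plane."""
    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(path.suffix + ".json")
    d = json.loads(path.read_text())
    return PlaneSpec(tuple(d["point"]), tuple(d["normal"]))
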
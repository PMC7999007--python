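"""Volumes and triangle meshes: containers, NIfTI/STL I/O, voxelization.

Axis convention used throughout the package: array axis 0 = x (subject
left-to-right), axis 1 = y (posterior-to-anterior), axis 2 = z
(inferior-to-superior).  Voxel indices are 0-based; the world position of a
voxel center is ``origin + index * spacing`` (millimetres).
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import trimesh
from skimage import measure

__all__ = [
    "Volume",
    "TriangleMesh",
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
    "voxelize_mesh",
    "volume_to_mesh",
]


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing and world origin.

    ``data`` holds graylevels (>= 0) or {0, 1} for binary masks; ``spacing``
    is the per-axis voxel size in mm; ``origin`` is the world position of
    voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("all grid dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def is_mask(self) -> bool:
        """True when the volume contains only values {0, 1}."""
        return bool(np.isin(np.unique(self.data), (0, 1)).all())

    def mask_array(self) -> np.ndarray:
        """Data as a boolean array; raises if the volume is not binary."""
        if not self.is_mask():
            raise ValueError("volume is not a binary mask")
        return self.data.astype(bool)

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to world mm (voxel-center convention)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def copy_with(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.spacing, self.origin)


@dataclass
class TriangleMesh:
    """A triangle surface mesh with vertices in world millimetres."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")
        if len(self.faces):
            a, b, c = self.faces.T
            if np.any((a == b) & (b == c)):
                raise ValueError("degenerate face: three identical vertices")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))


def _affine(volume: Volume) -> np.ndarray:
    aff = np.diag(list(volume.spacing) + [1.0])
    aff[:3, 3] = volume.origin
    return aff


def read_volume(path) -> Volume:
    """Read a NIfTI (.nii / .nii.gz) file into a :class:`Volume`.

    Spacing is taken from the header zooms (1 mm per axis if absent) and
    the origin from the affine translation.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise IOError(f"cannot read volume {path!s}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path!s}: expected 3D data, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    spacing = tuple(float(z) if z > 0 else 1.0 for z in zooms)
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume(data, spacing, origin)


def write_volume(volume: Volume, path) -> None:
    """Write a :class:`Volume` as NIfTI; integer data round-trips bit-exactly."""
    img = nib.Nifti1Image(volume.data, _affine(volume))
    img.header.set_zooms(volume.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot write volume to {path!s}: {exc}") from exc


def read_mesh(path) -> TriangleMesh:
    """Read an STL (binary or ASCII) file."""
    try:
        tm = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot read mesh {path!s}: {exc}") from exc
    return TriangleMesh.from_trimesh(tm)


def write_mesh(mesh: TriangleMesh, path) -> None:
    try:
        mesh.to_trimesh().export(str(path))
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot write mesh to {path!s}: {exc}") from exc


def _column_crossings(mesh: TriangleMesh, px: np.ndarray, py: np.ndarray):
    """z-values where vertical lines through (px, py) cross the surface.

    Vectorized even-odd ray casting: a triangle contributes a crossing to a
    column when the column's (x, y) lies inside the triangle's xy
    projection.  Returns a list of sorted crossing arrays, one per column.
    """
    tri = mesh.vertices[mesh.faces]  # (T, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    v0 = (b - a)[:, :2]
    v1 = (c - a)[:, :2]
    det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    ok = np.abs(det) > 1e-12
    a, b, c, v0, v1, det = a[ok], b[ok], c[ok], v0[ok], v1[ok], det[ok]
    # tiny deterministic offset avoids rays exactly through edges/vertices
    px = px + 1.23e-7
    py = py + 2.31e-7
    dpx = px[:, None] - a[None, :, 0]
    dpy = py[:, None] - a[None, :, 1]
    u = (dpx * v1[None, :, 1] - dpy * v1[None, :, 0]) / det[None, :]
    v = (dpy * v0[None, :, 0] - dpx * v0[None, :, 1]) / det[None, :]
    hit = (u >= 0) & (v >= 0) & (u + v <= 1)
    zc = (
        a[None, :, 2]
        + u * (b[None, :, 2] - a[None, :, 2])
        + v * (c[None, :, 2] - a[None, :, 2])
    )
    return [np.sort(zc[i][hit[i]]) for i in range(len(px))]


def voxelize_mesh(
    mesh: TriangleMesh,
    spacing: float | tuple[float, float, float] = 1.0,
    padding: int = 0,
    *,
    allow_open: bool = False,
) -> Volume:
    """Convert a closed triangle mesh into a filled binary mask volume.

    A voxel is foreground iff its *center* lies inside the mesh.  The grid
    covers the mesh bounding box plus ``padding`` voxels per side.

    Parameters
    ----------
    spacing:
        Voxel size in mm (scalar or per-axis).
    allow_open:
        When True, a non-watertight mesh is voxelized anyway (the inside
        test then depends on ray-parity and may be unreliable near holes).
    """
    if len(mesh.faces) == 0:
        raise ValueError("cannot voxelize an empty mesh")
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), 3).copy()
    if np.any(sp <= 0):
        raise ValueError("spacing must be positive")
    tm = mesh.to_trimesh()
    if not tm.is_watertight and not allow_open:
        raise ValueError(
            "mesh is not watertight (open surface); interior filling requires "
            "a closed mesh — pass allow_open=True to voxelize anyway"
        )
    lo, hi = tm.bounds
    n = np.maximum(np.ceil((hi - lo) / sp).astype(int), 1) + 2 * int(padding)
    origin = lo + sp / 2 - int(padding) * sp
    xs = origin[0] + sp[0] * np.arange(n[0])
    ys = origin[1] + sp[1] * np.arange(n[1])
    zs = origin[2] + sp[2] * np.arange(n[2])
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    crossings = _column_crossings(mesh, gx.ravel(), gy.ravel())
    inside = np.zeros((n[0] * n[1], n[2]), dtype=np.uint8)
    for i, zc in enumerate(crossings):
        if len(zc):
            # odd number of surface crossings above the center => inside
            inside[i] = (len(zc) - np.searchsorted(zc, zs)) % 2
    inside = inside.reshape(tuple(n))
    return Volume(inside, tuple(sp), tuple(origin))


def volume_to_mesh(volume: Volume, iso: float = 0.5) -> TriangleMesh:
    """Extract a closed isosurface mesh from a mask volume (marching cubes)."""
    mask = volume.mask_array()
    if not mask.any():
        raise ValueError("cannot extract a surface from an all-zero volume")
    if not 0 < iso < 1:
        raise ValueError(f"iso level must be in (0, 1), got {iso}")
    # pad so the surface closes at the grid boundary
    padded = np.pad(mask.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=iso, spacing=volume.spacing
    )
    verts = verts - np.asarray(volume.spacing) + np.asarray(volume.origin)
    return TriangleMesh(verts, faces)
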
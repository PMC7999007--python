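"""Synthetic skull phantoms with analytically known symmetry.

A phantom is an ellipsoidal cranial shell with two orbital holes and a
nasal aperture, built so that (absent deformation and noise) it is exactly
mirror-symmetric about the central sagittal voxel plane x = (nx - 1) / 2.
Phantoms stand in for segmented skull CT volumes: they let every later
stage (rotation classification, centroid extraction, midplane construction)
be validated against ground truth that real CT data cannot provide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from ._rotations import rotation_matrix
from .volume_io import Volume

__all__ = [
    "Deformation",
    "PhantomSpec",
    "AngleGrid",
    "RotationSample",
    "make_phantom",
    "render_rotated",
    "default_phantom_specs",
    "rotate_volume",
    "build_rotation_dataset",
    "RotationDataset",
]


@dataclass(frozen=True)
class Deformation:
    """A one-sided outward bulge of the cranial shell.

    ``side`` is 'left' (x below midplane) or 'right'; ``amplitude_mm`` is the
    extra outer semi-axis on that side; ``extent_mm`` limits the bulge to a
    band |y - cy| < extent around the coronal midline.
    """

    side: str = "left"
    amplitude_mm: float = 3.0
    extent_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.amplitude_mm < 0 or self.extent_mm <= 0:
            raise ValueError("amplitude must be >= 0 and extent > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one synthetic skull phantom (1 mm isotropic voxels).

    ``ridge_amp`` modulates the outer shell radius with fixed symmetric
    harmonics (suture-like corrugations).  Real skull surfaces carry dense
    boundary structure that makes sub-degree rotations detectable; a smooth
    ellipsoid does not, so the corrugations are part of the default
    geometry rather than an optional decoration.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    shell_radii: tuple[float, float, float] = (24.0, 28.0, 26.0)
    shell_thickness: float = 4.0
    orbit_radius: float = 6.0
    orbit_offset: tuple[float, float] = (10.0, 6.0)  # (lateral, vertical) mm
    nasal_width: float = 6.0
    ridge_amp: float = 0.10
    ridge_freq: tuple[float, float, float] = (5.0, 5.0, 4.0)
    deformation: Deformation | None = None
    noise_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 4:
            raise ValueError("grid_shape must be at least 4 voxels per axis")
        if min(self.shell_radii) <= 0 or self.shell_thickness <= 0:
            raise ValueError("shell radii and thickness must be positive")
        if self.shell_thickness >= min(self.shell_radii):
            raise ValueError("shell thickness must be below the smallest radius")
        half = np.asarray(self.grid_shape) / 2
        if np.any(np.asarray(self.shell_radii) >= half):
            raise ValueError(
                f"shell radii {self.shell_radii} exceed half the grid {tuple(half)}"
            )
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0, 1)")
        if self.ridge_amp < 0 or self.ridge_amp > 0.3:
            raise ValueError("ridge_amp must be in [0, 0.3]")

    def scaled(self, grid_shape: tuple[int, int, int]) -> "PhantomSpec":
        """The same relative geometry on a different grid."""
        f = min(grid_shape) / min(self.grid_shape)
        return PhantomSpec(
            grid_shape=tuple(grid_shape),
            shell_radii=tuple(r * f for r in self.shell_radii),
            shell_thickness=max(self.shell_thickness * f, 1.5),
            orbit_radius=max(self.orbit_radius * f, 1.5),
            orbit_offset=tuple(o * f for o in self.orbit_offset),
            nasal_width=max(self.nasal_width * f, 1.5),
            ridge_amp=self.ridge_amp,
            ridge_freq=self.ridge_freq,
            deformation=self.deformation,
            noise_rate=self.noise_rate,
        )


@dataclass(frozen=True)
class AngleGrid:
    """A symmetric grid of rotation angles (degrees)."""

    min_deg: float = -5.0
    max_deg: float = 5.0
    step_deg: float = 0.5

    def __post_init__(self) -> None:
        if self.step_deg <= 0:
            raise ValueError("step_deg must be positive")
        n = (self.max_deg - self.min_deg) / self.step_deg
        if n < 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"(max - min) / step must be a nonnegative integer, got {n}"
            )

    def __len__(self) -> int:
        return int(round((self.max_deg - self.min_deg) / self.step_deg)) + 1

    @property
    def angles(self) -> np.ndarray:
        return self.min_deg + self.step_deg * np.arange(len(self))

    def contains(self, deg: float, tol: float = 1e-9) -> bool:
        return bool(np.any(np.abs(self.angles - deg) <= tol))


@dataclass(frozen=True)
class RotationSample:
    volume: Volume
    coronal_deg: float
    transverse_deg: float
    base_id: int


def _eval_geometry(
    spec: PhantomSpec, xs: np.ndarray, ys: np.ndarray, zs: np.ndarray
) -> np.ndarray:
    """Evaluate the implicit phantom geometry at grid-centered coordinates.

    ``xs, ys, zs`` are coordinates relative to the grid center (any shape);
    every term depends on x only through |x|, so the symmetric phantom is
    exactly mirror-symmetric in x by construction.
    """
    x = np.abs(xs)
    y, z = ys, zs
    a, b, c = spec.shell_radii
    t = spec.shell_thickness

    def ellipsoid(ra, rb, rc):
        return (x / ra) ** 2 + (y / rb) ** 2 + (z / rc) ** 2

    rho2 = ellipsoid(a, b, c)
    if spec.ridge_amp > 0:
        # three orthogonal harmonic checkers: every rotation axis slides the
        # pattern across steep tangential gradients, so sub-voxel rotations
        # flip boundary voxels in both anatomical planes comparably
        fx, fy, fz = spec.ridge_freq
        wx = np.cos(fx * np.pi * x / a)
        wy = np.cos(fy * np.pi * y / b)
        wz = np.cos(fz * np.pi * z / c)
        w = (wx * wy + wy * wz + wz * wx) / 1.8
        outer = rho2 <= (1.0 + spec.ridge_amp * w) ** 2
    else:
        outer = rho2 <= 1.0
    inner = ellipsoid(a - t, b - t, c - t) <= 1.0
    shell = outer & ~inner

    if spec.deformation is not None:
        d = spec.deformation
        bulge = ellipsoid(a + d.amplitude_mm, b, c) <= 1.0
        side = xs < 0 if d.side == "left" else xs > 0
        shell |= bulge & ~inner & side & (np.abs(y) < d.extent_mm)

    # orbital holes: two spheres on the anterior face, symmetric in x
    ox, oz = spec.orbit_offset
    for sx in (-1.0, 1.0):
        dist2 = (xs - sx * ox) ** 2 + (y - b * 0.85) ** 2 + (z - oz) ** 2
        shell &= dist2 > spec.orbit_radius**2

    # nasal aperture: a vertical slot on the anterior midline
    slot = (
        (x < spec.nasal_width / 2)
        & (y > b * 0.6)
        & (z > -c * 0.35)
        & (z < c * 0.15)
    )
    shell &= ~slot
    return shell


def _eval_geometry_soft(
    spec: PhantomSpec, xs, ys, zs, edge_mm: float
) -> np.ndarray:
    """Smooth occupancy in [0, 1]: the implicit geometry with a sigmoid
    edge profile of width ``edge_mm``, emulating the point-spread blur of
    an acquisition.  Thresholding at 0.5 recovers the binary geometry up
    to the signed-distance approximation at each primitive's surface.
    """
    x = np.abs(xs)
    y, z = ys, zs
    a, b, c = spec.shell_radii
    t = spec.shell_thickness
    tau = edge_mm * 0.5

    def sig(d_mm):
        return 1.0 / (1.0 + np.exp(-d_mm / tau))

    def ell_sdist(ra, rb, rc, surface=1.0):
        # approximate signed distance (mm, positive inside)
        rho = np.sqrt((x / ra) ** 2 + (y / rb) ** 2 + (z / rc) ** 2)
        return (surface - rho) * ((ra + rb + rc) / 3.0)

    if spec.ridge_amp > 0:
        fx, fy, fz = spec.ridge_freq
        wx = np.cos(fx * np.pi * x / a)
        wy = np.cos(fy * np.pi * y / b)
        wz = np.cos(fz * np.pi * z / c)
        surface = 1.0 + spec.ridge_amp * (wx * wy + wy * wz + wz * wx) / 1.8
    else:
        surface = 1.0
    occ = sig(ell_sdist(a, b, c, surface))
    occ = occ * (1.0 - sig(ell_sdist(a - t, b - t, c - t)))

    if spec.deformation is not None:
        d = spec.deformation
        side = sig((xs if d.side == "right" else -xs) / 1.0)
        band = sig((d.extent_mm - np.abs(y)) / 1.0)
        bulge = (
            sig(ell_sdist(a + d.amplitude_mm, b, c))
            * (1.0 - sig(ell_sdist(a - t, b - t, c - t))) * side * band
        )
        occ = 1.0 - (1.0 - occ) * (1.0 - bulge)

    ox, oz = spec.orbit_offset
    for sx in (-1.0, 1.0):
        dist = np.sqrt(
            (xs - sx * ox) ** 2 + (y - b * 0.85) ** 2 + (z - oz) ** 2
        ) - spec.orbit_radius
        occ = occ * sig(dist)

    slot = (
        sig(spec.nasal_width / 2 - x) * sig(y - b * 0.6)
        * sig(z + c * 0.35) * sig(c * 0.15 - z)
    )
    return occ * (1.0 - slot)


def _apply_noise(mask: np.ndarray, rate: float, seed: int) -> np.ndarray:
    if rate <= 0:
        return mask
    rng = np.random.default_rng(seed)
    return mask ^ (rng.random(mask.shape) < rate)


def make_phantom(spec: PhantomSpec, seed: int = 0) -> Volume:
    """Build one phantom mask volume; deterministic given (spec, seed).

    The seed only drives the noise field; a noise-free symmetric spec yields
    a volume that equals its own x-axis reflection exactly.
    """
    return render_rotated(spec, 0.0, 0.0, seed=seed)


def render_rotated(
    spec: PhantomSpec,
    coronal_deg: float = 0.0,
    transverse_deg: float = 0.0,
    seed: int = 0,
    supersample: int = 1,
    soft_edge_mm: float = 0.0,
) -> Volume:
    """Render a phantom rigidly rotated in world space, exactly.

    The implicit geometry is evaluated on inverse-rotated voxel
    coordinates, which emulates a physically rotated object sampled by the
    scanner.  Unlike grid resampling, this preserves sub-voxel rotation
    information at any grid size: rotations smaller than the voxel pitch
    still move the boundary voxels they sweep past.

    Partial-volume modes (mutually exclusive; default is a binary mask):

    - ``supersample > 1`` evaluates the geometry at ``supersample**3``
      sub-voxel offsets and stores the occupied fraction — box-filter
      partial volume.
    - ``soft_edge_mm > 0`` evaluates a smooth sigmoid edge profile of that
      width — point-spread-function-like blur with continuous boundary
      intensities (the rotation classifiers train on this representation).

    Noise (if any) is applied after rotation, like acquisition noise; on
    graylevel renders a noise event inverts the voxel's occupancy.
    """
    if not np.isfinite([coronal_deg, transverse_deg]).all():
        raise ValueError("rotation angles must be finite")
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    if supersample > 1 and soft_edge_mm > 0:
        raise ValueError("choose either supersample or soft_edge_mm, not both")
    n = np.asarray(spec.grid_shape)
    center = (n - 1) / 2
    shape = tuple(spec.grid_shape)
    R = rotation_matrix(coronal_deg, transverse_deg)
    idx = np.indices(shape, dtype=np.float64).reshape(3, -1)
    if soft_edge_mm > 0:
        src = R.T @ (idx - center[:, None])
        frac = _eval_geometry_soft(
            spec, src[0], src[1], src[2], soft_edge_mm
        ).reshape(shape)
    elif supersample == 1:
        src = R.T @ (idx - center[:, None])  # inverse-rotate voxel coords
        mask = _eval_geometry(
            spec, src[0].reshape(shape), src[1].reshape(shape),
            src[2].reshape(shape),
        )
        mask = _apply_noise(mask, spec.noise_rate, seed)
        return Volume(mask.astype(np.uint8))
    else:
        ss = supersample
        offs = (np.arange(ss) + 0.5) / ss - 0.5
        ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
        sub = np.stack([ox.ravel(), oy.ravel(), oz.ravel()])  # (3, ss^3)
        # all sub-voxel sample points in one geometry evaluation
        pts = (idx[:, None, :] + sub[:, :, None]).reshape(3, -1)
        src = R.T @ (pts - center[:, None])
        occ = _eval_geometry(spec, src[0], src[1], src[2])
        frac = occ.reshape(ss**3, -1).mean(axis=0).reshape(shape)
    if spec.noise_rate > 0:
        rng = np.random.default_rng(seed)
        flips = rng.random(shape) < spec.noise_rate
        frac = np.where(flips, 1.0 - frac, frac)
    return Volume(frac.astype(np.float32))


def default_phantom_specs(
    n: int,
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    seed: int = 0,
    **overrides,
) -> list[PhantomSpec]:
    """``n`` symmetric phantom specs with jittered geometry (one per subject).

    Radii, thickness and aperture parameters are jittered by up to ~8% around
    the defaults so the specs emulate inter-subject anatomical variation
    while each phantom remains exactly bilaterally symmetric.
    """
    rng = np.random.default_rng(seed)
    base = PhantomSpec().scaled(grid_shape)
    specs = []
    for _ in range(n):
        j = lambda v, lo=0.92, hi=1.08: float(v * rng.uniform(lo, hi))  # noqa: E731
        specs.append(
            PhantomSpec(
                grid_shape=tuple(grid_shape),
                shell_radii=tuple(j(r) for r in base.shell_radii),
                shell_thickness=j(base.shell_thickness),
                orbit_radius=j(base.orbit_radius),
                orbit_offset=tuple(j(o) for o in base.orbit_offset),
                nasal_width=j(base.nasal_width),
                **overrides,
            )
        )
    return specs


def rotate_volume(
    volume: Volume, coronal_deg: float, transverse_deg: float
) -> Volume:
    """Rigidly rotate a volume about its grid center (nearest-neighbor).

    Coronal angle rotates about the y axis, transverse about the z axis,
    composed as ``R_z(transverse) @ R_y(coronal)``.  Voxels mapped from
    outside the grid fill with 0; the grid shape is unchanged.  Rotation is
    performed in index space, which is rigid in world space only for
    isotropic spacing (the phantom default).
    """
    if not np.isfinite([coronal_deg, transverse_deg]).all():
        raise ValueError("rotation angles must be finite")
    if coronal_deg == 0.0 and transverse_deg == 0.0:
        return volume.copy_with(volume.data.copy())
    R = rotation_matrix(coronal_deg, transverse_deg)
    center = (np.asarray(volume.shape) - 1) / 2
    # affine_transform maps output coords to input coords: i = M @ o + off
    M = R.T
    offset = center - M @ center
    out = ndimage.affine_transform(
        volume.data, M, offset=offset, order=0, mode="constant", cval=0,
        output=volume.data.dtype,
    )
    return volume.copy_with(out)


class RotationDataset:
    """Lazy enumeration of every (base, coronal, transverse) rotation.

    Samples are generated on demand in deterministic (base, coronal,
    transverse) order; the dataset never materializes all volumes at once.
    A base given as a :class:`Volume` is rotated by nearest-neighbor grid
    resampling; a base given as a :class:`PhantomSpec` is re-rendered
    analytically at each rotation (exact, resolution-independent — the
    preferred path for classifier training data).
    """

    def __init__(
        self,
        bases: Sequence[Volume | PhantomSpec],
        grid: AngleGrid,
        seed: int = 0,
        supersample: int = 1,
        soft_edge_mm: float = 0.6,
    ):
        if len(bases) == 0:
            raise ValueError("need at least one base volume")
        self.bases = list(bases)
        self.grid = grid
        self.seed = seed
        self.supersample = supersample
        self.soft_edge_mm = soft_edge_mm
        self._angles = grid.angles

    def __len__(self) -> int:
        return len(self.bases) * len(self.grid) ** 2

    def __getitem__(self, i: int) -> RotationSample:
        if not 0 <= i < len(self):
            raise IndexError(i)
        k = len(self.grid)
        b, rest = divmod(i, k * k)
        ci, ti = divmod(rest, k)
        cor, tra = float(self._angles[ci]), float(self._angles[ti])
        base = self.bases[b]
        if isinstance(base, PhantomSpec):
            vol = render_rotated(base, cor, tra, seed=(self.seed + i) % 2**31,
                                 supersample=self.supersample,
                                 soft_edge_mm=self.soft_edge_mm)
        else:
            vol = rotate_volume(base, cor, tra)
        return RotationSample(vol, cor, tra, base_id=b)

    def __iter__(self) -> Iterator[RotationSample]:
        for i in range(len(self)):
            yield self[i]

    def labels(self) -> tuple[np.ndarray, np.ndarray]:
        """(coronal_deg, transverse_deg) arrays for all samples, no volumes."""
        k = len(self.grid)
        cor = np.tile(np.repeat(self._angles, k), len(self.bases))
        tra = np.tile(self._angles, k * len(self.bases))
        return cor, tra


def build_rotation_dataset(
    bases: Sequence[Volume | PhantomSpec],
    grid: AngleGrid = AngleGrid(),
    seed: int = 0,
    supersample: int = 1,
    soft_edge_mm: float = 0.6,
) -> RotationDataset:
    """Expand base volumes (or phantom specs) over the full joint grid.

    Spec bases are re-rendered analytically per rotation; the default
    0.6 mm soft edge stores smooth partial-volume graylevels, the
    classifiers' training representation (see :func:`render_rotated`).
    Pass ``soft_edge_mm=0`` for binary renders.
    """
    return RotationDataset(bases, grid, seed=seed, supersample=supersample,
                           soft_edge_mm=soft_edge_mm)
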
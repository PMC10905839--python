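"""Axis-aligned 3D scalar volumes with physical geometry.

The pipeline works on slice-to-volume-reconstructed (SVR) fetal head MRI,
which is axis-aligned by construction (nominally 0.8 mm isotropic).  A
:class:`VoxelGrid` therefore carries only per-axis spacing, the world
position of the first voxel centre, and an anatomical orientation code per
axis -- a deliberate restriction compared to a general NIfTI affine.
Oblique geometries are rejected at load time.

World convention: voxel indices are 0-based and address voxel *centres*;
the world coordinate of voxel ``(i, j, k)`` is obtained from the grid
affine (permutation/flip times ``diag(spacing)`` plus ``origin``).  The
canonical anatomical frame used throughout the package is LPS
(left-posterior-superior, the radiological/DICOM patient frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

#: Canonical anatomical frame: radiological (DICOM patient) convention.
CANONICAL_AXCODES = ("L", "P", "S")

# world axis index and sign *in the LPS frame* for each orientation code:
# +x = Left, +y = Posterior, +z = Superior
_CODE_AXIS = {"L": (0, +1), "R": (0, -1),
              "P": (1, +1), "A": (1, -1),
              "S": (2, +1), "I": (2, -1)}
_AXIS_CODE = {(0, +1): "L", (0, -1): "R", (1, +1): "P", (1, -1): "A",
              (2, +1): "S", (2, -1): "I"}
# LPS flips the first two axes of nibabel's native RAS+ frame
_LPS_FLIP = np.array([-1.0, -1.0, 1.0])


class GridError(ValueError):
    """Raised for invalid volume files or geometry."""


@dataclass
class VoxelGrid:
    """A 3D scalar field on an axis-aligned physical grid.

    Parameters
    ----------
    data
        3D array, arbitrary intensity units.
    spacing
        Per-axis voxel size in mm, all components positive.
    origin
        World (LPS, mm) position of the centre of voxel ``(0, 0, 0)``.
    axis_codes
        One of ``R/L/A/P/S/I`` per data axis, e.g. ``("L", "P", "S")``.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    axis_codes: tuple = CANONICAL_AXCODES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GridError(f"expected 3 axes, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise GridError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.axis_codes = tuple(self.axis_codes)
        axes = sorted(_CODE_AXIS[c][0] for c in self.axis_codes)
        if axes != [0, 1, 2]:
            raise GridError(f"axis codes {self.axis_codes} do not span 3 axes")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (LPS, mm) affine."""
        A = np.zeros((4, 4))
        A[3, 3] = 1.0
        for axis, code in enumerate(self.axis_codes):
            w, sign = _CODE_AXIS[code]
            A[w, axis] = sign * self.spacing[axis]
        A[:3, 3] = self.origin
        return A

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """World (mm) coordinates of (fractional) voxel indices, shape (n, 3)."""
        ijk = np.atleast_2d(ijk)
        A = self.affine
        return ijk @ A[:3, :3].T + A[:3, 3]

    def voxel_coords(self, xyz: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`world_coords` (fractional indices)."""
        xyz = np.atleast_2d(xyz)
        A = self.affine
        return (xyz - A[:3, 3]) @ np.linalg.inv(A[:3, :3]).T

    def sample_world(self, xyz: np.ndarray, order: int = 1,
                     cval: float = 0.0) -> np.ndarray:
        """Interpolate the field at world-space points (trilinear default)."""
        ijk = self.voxel_coords(xyz)
        return map_coordinates(self.data.astype(np.float64, copy=False),
                               ijk.T, order=order, mode="constant", cval=cval)

    def copy_with(self, **kw) -> "VoxelGrid":
        if "data" not in kw:
            kw["data"] = self.data.copy()
        return replace(self, **kw)

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=tol)
                and np.allclose(self.origin, other.origin, atol=tol)
                and self.axis_codes == other.axis_codes)


@dataclass
class BinaryMask(VoxelGrid):
    """A :class:`VoxelGrid` whose values are exactly 0 or 1."""

    def __post_init__(self):
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise GridError("mask values must be exactly 0 or 1")
        self.data = self.data.astype(np.uint8)

    @classmethod
    def from_grid(cls, grid: VoxelGrid, data=None) -> "BinaryMask":
        d = grid.data if data is None else data
        return cls(data=np.asarray(d) > 0, spacing=grid.spacing,
                   origin=grid.origin, axis_codes=grid.axis_codes)


# -- NIfTI I/O ------------------------------------------------------------

def _grid_from_nifti(img) -> VoxelGrid:
    affine = img.affine
    if not np.isfinite(affine).all() or np.linalg.det(affine[:3, :3]) == 0:
        raise GridError("non-invertible affine")
    R = affine[:3, :3]
    # reject oblique geometry: each column must align with one world axis
    absR = np.abs(R)
    for axis in range(3):
        col = absR[:, axis]
        if col.max() < (1 - 1e-4) * np.linalg.norm(col):
            raise GridError("oblique geometry is not supported (SVR volumes "
                            "are axis-aligned); resample externally first")
    codes = []
    spacing = []
    for axis in range(3):
        w = int(np.argmax(absR[:, axis]))
        sign = 1 if R[w, axis] > 0 else -1
        # nibabel affines are RAS+; convert to LPS by flipping x and y
        lps_sign = sign * (-1 if w < 2 else 1)
        codes.append(_AXIS_CODE[(w, lps_sign)])
        spacing.append(float(absR[w, axis]))
    origin_ras = affine[:3, 3]
    origin = origin_ras * _LPS_FLIP

    data = np.asanyarray(img.dataobj)  # applies header slope/intercept
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GridError(f"expected a 3D volume, got shape {data.shape}")
    return VoxelGrid(data=np.asarray(data), spacing=tuple(spacing),
                     origin=tuple(origin), axis_codes=tuple(codes))


def read_volume(path) -> VoxelGrid:
    """Read a 3D single-channel NIfTI-1 volume.

    Header slope/intercept are applied; a trailing singleton 4th axis is
    squeezed; oblique affines are rejected with a diagnostic.
    """
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise GridError(f"no such file: {path}")
    return _grid_from_nifti(img)


def read_mask(path) -> BinaryMask:
    g = read_volume(path)
    return BinaryMask.from_grid(g)


def write_volume(grid: VoxelGrid, path) -> None:
    """Write a grid as NIfTI-1, reproducing spacing/origin/orientation.

    Binary masks are stored with an integer dtype.
    """
    A = grid.affine.copy()
    # back to nibabel's RAS+ convention
    A[:2, :] *= -1
    data = grid.data
    if isinstance(grid, BinaryMask):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, A)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


# -- reorientation --------------------------------------------------------

def reorient_to_radiological(grid: VoxelGrid) -> VoxelGrid:
    """Permute/flip axes so ``axis_codes == CANONICAL_AXCODES`` (LPS).

    The world position of every voxel is unchanged; only the storage order
    changes.  Idempotent.
    """
    if grid.axis_codes == CANONICAL_AXCODES:
        return grid
    # target world axis for each current data axis, and whether to flip
    world_axis = []
    flips = []
    for code in grid.axis_codes:
        w, sign = _CODE_AXIS[code]
        target_sign = _CODE_AXIS[CANONICAL_AXCODES[w]][1]
        world_axis.append(w)
        flips.append(sign != target_sign)

    data = grid.data
    origin = np.array(grid.origin, dtype=float)
    A = grid.affine
    for axis, flip in enumerate(flips):
        if flip:
            n = data.shape[axis]
            data = np.flip(data, axis=axis)
            origin = origin + A[:3, axis] * (n - 1)
    perm = np.argsort(world_axis)  # data axis order so axis a -> world a
    data = np.transpose(data, perm)
    spacing = tuple(grid.spacing[p] for p in perm)
    out = VoxelGrid(data=np.ascontiguousarray(data), spacing=spacing,
                    origin=tuple(origin), axis_codes=CANONICAL_AXCODES)
    if isinstance(grid, BinaryMask):
        out = BinaryMask.from_grid(out)
    return out
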
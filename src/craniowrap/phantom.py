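"""Synthetic fetal-head phantoms with exact ground truth.

Every downstream stage (preprocessing, segmentation training, surface
extraction, refinement, print export) is exercised on these phantoms, so
they emulate the features that drive each stage of a T2w single-shot TSE
fetal acquisition:

* a bright amniotic-fluid background and a darker soft-tissue head
  (T2w polarity; configurable inversion),
* an ellipsoidal cranium with protruding face features -- nose, lips,
  chin and two thin ear flaps (the structures the low-resolution
  segmentation tends to lose and the refinement must recover),
* optionally a slab of maternal tissue touching the scalp (the principal
  real-world failure mode: a tissue/tissue interface with no fluid gap),
* a smooth multiplicative bias field and additive Gaussian noise.

Geometry is constructive solid geometry on implicit ellipsoids evaluated
at voxel centres, so the ground-truth surface is known analytically and
the voxel mask is exact at grid resolution.  The solid is a union of
ellipsoids that all overlap the cranium, hence is guaranteed to be one
connected component with spherical topology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, VoxelGrid

# axis convention within the phantom: x lateral, y anterior(+ = face), z superior


@dataclass
class FaceFeature:
    """One protruding face feature: an ellipsoid glued onto the cranium.

    ``center_offset`` is the centre position in *unit-cranium* coordinates
    (so (0, 1, 0) lies on the front scalp); ``semi_axes`` are in mm.
    """

    semi_axes: tuple
    center_offset: tuple


def default_face_features() -> dict:
    """Nose, lips, chin and two thin ear flaps (sizes in mm).

    The ears are ~2.4 mm thick elliptical flaps protruding 3-8 mm
    laterally from the scalp, matching late second / third trimester
    pinna dimensions at the 0.8 mm working resolution.
    """
    return {
        "nose": FaceFeature((6.0, 8.0, 9.0), (0.0, 0.98, -0.15)),
        "lips": FaceFeature((9.0, 5.0, 5.5), (0.0, 0.97, -0.42)),
        "chin": FaceFeature((8.0, 6.0, 6.0), (0.0, 0.85, -0.70)),
        "ear_left": FaceFeature((5.5, 1.2, 8.0), (1.02, -0.05, -0.05)),
        "ear_right": FaceFeature((5.5, 1.2, 8.0), (-1.02, -0.05, -0.05)),
    }


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic fetal head.

    Defaults model a ~28-32 week head imaged at 0.8 mm isotropic: cranium
    semi-axes ~(35, 30, 42) mm in a 120 mm field of view, fluid brighter
    than tissue (T2w), 15 % bias amplitude, sigma = 0.03 additive noise on
    a [0, 1]-ish intensity scale.  ``seed`` drives noise/bias *and* a mild
    (+/- 8 %) anatomical size jitter so a population of phantoms with
    consecutive seeds spans a plausible biometric range; set
    ``anatomy_jitter = 0`` for a fixed geometry.
    """

    head_radii: tuple = (35.0, 30.0, 42.0)
    face_features: dict = field(default_factory=default_face_features)
    fluid_intensity: float = 1.0
    tissue_intensity: float = 0.45
    maternal_intensity: float = 0.52
    adjacent_tissue: bool = False
    contact_patch_mm: float = 25.0
    bias_amplitude: float = 0.15
    noise_sigma: float = 0.03
    spacing_mm: float = 0.8
    fov_mm: float = 120.0
    anatomy_jitter: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if any(r <= 0 for r in self.head_radii):
            raise ValueError("head_radii must be positive")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.fluid_intensity == self.tissue_intensity:
            raise ValueError("fluid and tissue intensity must differ")


def _ellipsoid_mask(coords, center, semi_axes):
    x, y, z = coords
    return (((x - center[0]) / semi_axes[0]) ** 2
            + ((y - center[1]) / semi_axes[1]) ** 2
            + ((z - center[2]) / semi_axes[2]) ** 2) <= 1.0


def _smooth_bias(shape, amplitude, rng):
    """Low-frequency multiplicative field in [1-a, 1+a]."""
    coarse = rng.standard_normal((4, 4, 4))
    fine = ndimage.zoom(coarse, [s / 4 for s in shape], order=3)
    fine = fine[: shape[0], : shape[1], : shape[2]]
    pad = [(0, shape[i] - fine.shape[i]) for i in range(3)]
    fine = np.pad(fine, pad, mode="edge")
    m = np.abs(fine).max()
    if m > 0:
        fine = fine / m
    return 1.0 + amplitude * fine


def generate_phantom(spec: PhantomSpec):
    """Render a phantom.

    Returns
    -------
    image : VoxelGrid
        Piecewise-constant intensities times a smooth bias field plus
        Gaussian noise.  Bit-reproducible from ``spec.seed``.
    truth : BinaryMask
        Head solid (cranium union face features); one 6-connected
        component with spherical topology.
    regions : dict
        Per-feature world-mm bounding boxes ``{name: (lo, hi)}`` for
        region-restricted evaluation (e.g. ear-recovery tests).
    """
    rng = np.random.default_rng(spec.seed)
    jit = spec.anatomy_jitter
    scale = 1.0 + rng.uniform(-jit, jit) if jit > 0 else 1.0
    radii = np.array(spec.head_radii) * scale

    n = int(round(spec.fov_mm / spec.spacing_mm))
    s = spec.spacing_mm
    shape = (n, n, n)
    # world coordinates of voxel centres, origin at FOV corner
    ax = (np.arange(n) * s)
    center = np.array([ax[-1] / 2.0] * 3)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    coords = (X, Y, Z)

    if (radii.max() + 10) * 2 > spec.fov_mm:
        raise ValueError("head does not fit in the field of view")

    truth = _ellipsoid_mask(coords, center, radii)
    regions = {}
    for name, feat in spec.face_features.items():
        f_scale = scale * (1.0 + rng.uniform(-jit, jit) if jit > 0 else 1.0)
        semi = np.array(feat.semi_axes) * f_scale
        c = center + np.array(feat.center_offset) * radii
        if ((c - semi) < 0).any() or ((c + semi) > ax[-1]).any():
            raise ValueError(f"feature {name!r} exceeds the volume")
        truth |= _ellipsoid_mask(coords, c, semi)
        regions[name] = (tuple(c - semi - 2 * s), tuple(c + semi + 2 * s))

    # the union of overlapping convex solids is genus 0 in the continuum;
    # enforce the same for the voxelization (coarse grids can pinch thin
    # gaps between features into handles or cavities)
    truth = ndimage.binary_fill_holes(truth)
    from skimage.measure import euler_number

    if euler_number(truth, connectivity=1) != 1:
        truth = ndimage.binary_fill_holes(
            ndimage.binary_closing(truth, ndimage.generate_binary_structure(3, 1)))
        if euler_number(truth, connectivity=1) != 1:
            raise ValueError("phantom voxelization is not genus 0 at this "
                             "resolution; increase spacing_mm resolution")

    image = np.where(truth, spec.tissue_intensity, spec.fluid_intensity)

    if spec.adjacent_tissue:
        # spherical maternal wall cap touching the back of the scalp
        patch = spec.contact_patch_mm
        wall_r = 80.0
        wall_c = center + np.array([0.0, -(radii[1] + wall_r - 1.0), 0.0])
        wall = _ellipsoid_mask(coords, wall_c, (wall_r, wall_r, wall_r))
        near = _ellipsoid_mask(coords, center + [0, -radii[1], 0],
                               (patch, patch, patch))
        wall &= near & ~truth
        image = np.where(wall, spec.maternal_intensity, image)

    if spec.bias_amplitude > 0:
        image = image * _smooth_bias(shape, spec.bias_amplitude, rng)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, shape)

    geom = dict(spacing=(s, s, s), origin=(0.0, 0.0, 0.0))
    img = VoxelGrid(data=image.astype(np.float32), **geom)
    msk = BinaryMask(data=truth, **geom)
    return img, msk, regions


def degrade_mask(truth: BinaryMask, blur_mm: float,
                 threshold: float = 0.5) -> BinaryMask:
    """Emulate a coarse network segmentation by blurring and re-thresholding.

    Gaussian smoothing at ``blur_mm`` (physical mm) followed by a
    threshold in (0, 1) erases thin protrusions such as the ear flaps --
    the defect the surface refinement stage is designed to repair.  With
    ``blur_mm = 0`` the mask is returned unchanged.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    if blur_mm == 0:
        return truth.copy_with()
    sigma_vox = [blur_mm / s for s in truth.spacing]
    soft = ndimage.gaussian_filter(truth.data.astype(np.float32), sigma_vox)
    out = soft > threshold
    # keep the contract: degraded mask never escapes a one-blur dilation
    out &= ndimage.binary_dilation(
        truth.data > 0, iterations=max(1, int(np.ceil(blur_mm / min(truth.spacing)))))
    return BinaryMask.from_grid(truth, out)


def save_regions(regions: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump({k: [list(lo), list(hi)] for k, (lo, hi) in regions.items()},
                  fh, indent=1)


def load_regions(path) -> dict:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: (tuple(v[0]), tuple(v[1])) for k, v in raw.items()}
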
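"""NEMA IEC body-phantom geometry and voxelization.

The phantom is the six-hot-sphere image-quality phantom (sphere diameters
10-37 mm on a 114.4-mm circle) inside a torso-shaped water hull, used
without the lung insert.  The hull cross-section is modelled as a 70-mm-tall
rectangle capped by two half-ellipses (interior width 300 mm, total height
230 mm, axial length 180 mm) -- standard phantom dimensions; the original
study gives none.

Coordinates are physical millimetres, origin at the phantom center, x to
the right, y anterior, z axial.  Voxel (0,0,0) center sits at ``origin``;
indices are 0-based with half-open voxel extents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "NEMA_SPHERE_DIAMETERS_MM",
    "MU_WATER_PER_CM",
    "PhantomSpec",
    "VoxelVolume",
    "sphere_volume",
    "printed_sphere_volumes",
    "default_sphere_centers",
    "voxelize",
    "background_voi",
    "mask_volume_liters",
]

NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
SPHERE_CIRCLE_DIAMETER_MM = 114.4

# Narrow-beam linear attenuation of water at the two AC energies, per cm.
MU_WATER_PER_CM = {80: 0.184, 240: 0.127}

HULL_WIDTH_MM = 300.0
HULL_HEIGHT_MM = 230.0
HULL_LENGTH_MM = 180.0
_RECT_HALF_HEIGHT = 35.0  # central rectangle is 70 mm tall
_ELLIPSE_B = (HULL_HEIGHT_MM - 2 * _RECT_HALF_HEIGHT) / 2.0  # 80 mm semi-axis


class InvalidSpecError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    pass


def sphere_volume(diameter_mm: float) -> float:
    """Sphere volume in mL, (pi/6) d^3 with d in mm."""
    if diameter_mm <= 0:
        raise InvalidSpecError("diameter must be > 0")
    return math.pi / 6.0 * diameter_mm**3 / 1000.0


def printed_sphere_volumes(diameters_mm=NEMA_SPHERE_DIAMETERS_MM) -> list[float]:
    """Sphere volumes truncated (not rounded) to 0.01 mL.

    The vendor phantom sheet truncates: (pi/6)*22^3 = 5.5753 mL is listed
    as 5.57, and the listed volumes sum to 47.82 mL only when truncated.
    """
    return [math.floor(sphere_volume(d) * 100.0) / 100.0 for d in diameters_mm]


def default_sphere_centers(rotation_deg: float = 0.0) -> np.ndarray:
    """Six sphere centers on the standard 114.4-mm circle, z = 0 plane.

    Returned in the same order as ``NEMA_SPHERE_DIAMETERS_MM`` (ascending
    diameter); the largest sphere sits at angle ``rotation_deg``, the others
    follow at 60-degree steps (28 mm at +60, ..., 10 mm at +300).
    """
    r = SPHERE_CIRCLE_DIAMETER_MM / 2.0
    centers = np.zeros((6, 3))
    # largest first going around, then reorder ascending to match diameters
    for k, idx in enumerate([5, 4, 3, 2, 1, 0]):  # diameter index placed at step k
        ang = math.radians(rotation_deg + 60.0 * k)
        centers[idx] = (r * math.cos(ang), r * math.sin(ang), 0.0)
    return centers


def _inside_hull(x, y, z, length_mm=HULL_LENGTH_MM):
    """Vectorized membership test for the torso hull."""
    half_w = HULL_WIDTH_MM / 2.0
    in_axial = np.abs(z) <= length_mm / 2.0
    ay = np.abs(y)
    in_rect = (np.abs(x) <= half_w) & (ay <= _RECT_HALF_HEIGHT)
    in_ell = (x / half_w) ** 2 + (
        np.maximum(ay - _RECT_HALF_HEIGHT, 0.0) / _ELLIPSE_B
    ) ** 2 <= 1.0
    return in_axial & (in_rect | (in_ell & (ay > _RECT_HALF_HEIGHT)))


@dataclass
class PhantomSpec:
    """Geometric definition of the sphere phantom.

    ``sphere_concentrations`` are in kBq/mL (one per sphere);
    ``background_concentration`` fills the hull outside the spheres.
    """

    sphere_diameters: tuple = NEMA_SPHERE_DIAMETERS_MM
    sphere_centers: np.ndarray | None = None
    sphere_concentrations: tuple = (30.0,) * 6
    background_concentration: float = 0.0
    hull_length_mm: float = HULL_LENGTH_MM
    attenuation_medium: str = "water"

    def __post_init__(self) -> None:
        if self.sphere_centers is None:
            self.sphere_centers = default_sphere_centers()
        self.sphere_centers = np.asarray(self.sphere_centers, dtype=float)
        d = np.asarray(self.sphere_diameters, dtype=float)
        if d.size != 6 or self.sphere_centers.shape != (6, 3):
            raise InvalidSpecError("phantom requires exactly six spheres")
        if len(self.sphere_concentrations) != 6:
            raise InvalidSpecError("one concentration per sphere required")
        if not np.all(np.diff(d) > 0):
            raise InvalidSpecError("sphere diameters must be strictly increasing")
        # pairwise non-overlap
        for i in range(6):
            for j in range(i + 1, 6):
                gap = np.linalg.norm(self.sphere_centers[i] - self.sphere_centers[j])
                if gap < (d[i] + d[j]) / 2.0:
                    raise InvalidSpecError(f"spheres {i} and {j} overlap")
        # spheres fully inside hull: test a surface point sample
        for i in range(6):
            c = self.sphere_centers[i]
            rad = d[i] / 2.0
            for ax in range(3):
                for sgn in (-1, 1):
                    p = c.copy()
                    p[ax] += sgn * rad
                    if not bool(_inside_hull(p[0], p[1], p[2], self.hull_length_mm)):
                        raise InvalidSpecError(f"sphere {i} extends outside hull")

    def total_activity_kbq(self) -> float:
        """Sum of concentration x volume over spheres plus background."""
        act = sum(
            c * sphere_volume(d)
            for c, d in zip(self.sphere_concentrations, self.sphere_diameters)
        )
        return float(act)

    def to_yaml(self, path) -> None:
        data = {
            "sphere_diameters": [float(v) for v in self.sphere_diameters],
            "sphere_centers": np.asarray(self.sphere_centers).tolist(),
            "sphere_concentrations": [float(v) for v in self.sphere_concentrations],
            "background_concentration": float(self.background_concentration),
            "hull_length_mm": float(self.hull_length_mm),
            "attenuation_medium": self.attenuation_medium,
        }
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        data = yaml.safe_load(Path(path).read_text())
        data["sphere_diameters"] = tuple(data["sphere_diameters"])
        data["sphere_concentrations"] = tuple(data["sphere_concentrations"])
        data["sphere_centers"] = np.asarray(data["sphere_centers"])
        return cls(**data)


@dataclass
class VoxelVolume:
    """Isotropic voxel grid with physical geometry.

    ``origin`` is the physical position (mm) of the center of voxel
    (0, 0, 0); axis order is (x, y, z), right/anterior/axial.
    """

    values: np.ndarray
    spacing: float = 2.40
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    frame: str = "xyz-ras"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise InvalidSpecError("spacing must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise InvalidSpecError("voxel values must be finite")

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        return self.spacing**3 / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing * np.arange(n)

    def index_of(self, point_mm) -> tuple[int, int, int]:
        """Nearest voxel index of a physical point."""
        idx = np.rint((np.asarray(point_mm) - self.origin) / self.spacing)
        return tuple(int(v) for v in idx)

    def like(self, values: np.ndarray) -> "VoxelVolume":
        return replace(self, values=values)

    # ---- I/O -------------------------------------------------------------
    def save(self, path) -> None:
        path = str(path)
        if path.endswith(".mha") or path.endswith(".mhd"):
            import SimpleITK as sitk

            img = sitk.GetImageFromArray(
                np.ascontiguousarray(self.values.astype(np.float32).T)
            )
            img.SetSpacing((self.spacing,) * 3)
            img.SetOrigin(tuple(float(v) for v in self.origin))
            sitk.WriteImage(img, path)
        else:
            import nibabel as nib

            affine = np.diag([self.spacing] * 3 + [1.0])
            affine[:3, 3] = self.origin
            nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), path)

    @classmethod
    def load(cls, path) -> "VoxelVolume":
        path = str(path)
        if path.endswith(".mha") or path.endswith(".mhd"):
            import SimpleITK as sitk

            img = sitk.ReadImage(path)
            values = sitk.GetArrayFromImage(img).T
            spacing = float(img.GetSpacing()[0])
            origin = np.asarray(img.GetOrigin(), dtype=float)
        else:
            import nibabel as nib

            img = nib.load(path)
            values = np.asarray(img.dataobj, dtype=np.float64)
            spacing = float(img.affine[0, 0])
            origin = np.asarray(img.affine[:3, 3], dtype=float)
        return cls(values=np.asarray(values, dtype=np.float64), spacing=spacing,
                   origin=origin)


def _grid_for(spec: PhantomSpec, spacing: float, shape=None):
    """Grid shape/origin covering the hull, centered on the phantom."""
    if shape is None:
        nx = int(math.ceil(HULL_WIDTH_MM / spacing)) + 2
        ny = int(math.ceil(HULL_HEIGHT_MM / spacing)) + 2
        nz = int(math.ceil(spec.hull_length_mm / spacing)) + 2
        shape = (nx, ny, nz)
    origin = -(np.asarray(shape) - 1) / 2.0 * spacing
    return tuple(shape), origin


def voxelize(
    spec: PhantomSpec,
    spacing: float,
    mu_per_cm: float,
    shape=None,
    subsample: int = 1,
) -> tuple[VoxelVolume, VoxelVolume]:
    """Discretize the phantom into activity (kBq/mL) and mu (per cm) volumes.

    Region membership is by voxel-center test; with ``subsample`` = s > 1
    each voxel is sampled at s^3 interior points (>= 8) and the activity is
    the partial-volume average, which permits spacings coarser than the
    smallest sphere radius.
    """
    d = np.asarray(spec.sphere_diameters, dtype=float)
    if subsample < 1:
        raise InvalidSpecError("subsample must be >= 1")
    if subsample == 1 and spacing > d[0] / 2.0:
        raise InvalidSpecError(
            "spacing must be <= smallest sphere radius unless subsampling is enabled"
        )
    shape, origin = _grid_for(spec, spacing, shape)
    nx, ny, nz = shape
    xs = origin[0] + spacing * np.arange(nx)
    ys = origin[1] + spacing * np.arange(ny)
    zs = origin[2] + spacing * np.arange(nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    hull = _inside_hull(X, Y, Z, spec.hull_length_mm)
    activity = np.where(hull, float(spec.background_concentration), 0.0)

    if subsample > 1:
        offs = (np.arange(subsample) + 0.5) / subsample - 0.5  # fractions of a voxel
        sub = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), -1).reshape(-1, 3)
        sub *= spacing

    for i in range(6):
        c = spec.sphere_centers[i]
        rad = d[i] / 2.0
        conc = float(spec.sphere_concentrations[i])
        # bounding box in voxel indices
        lo = np.floor((c - rad - spacing - origin) / spacing).astype(int)
        hi = np.ceil((c + rad + spacing - origin) / spacing).astype(int) + 1
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        Xb, Yb, Zb = X[sl], Y[sl], Z[sl]
        if subsample == 1:
            inside = (Xb - c[0]) ** 2 + (Yb - c[1]) ** 2 + (Zb - c[2]) ** 2 <= rad**2
            frac = inside.astype(float)
        else:
            pts = np.stack([Xb, Yb, Zb], axis=-1)[..., None, :] + sub
            r2 = ((pts - c) ** 2).sum(axis=-1)
            frac = (r2 <= rad**2).mean(axis=-1)
        activity[sl] = activity[sl] * (1.0 - frac) + conc * frac

    mu = np.where(hull, float(mu_per_cm), 0.0)
    act_vol = VoxelVolume(values=activity, spacing=spacing, origin=origin)
    mu_vol = VoxelVolume(values=mu, spacing=spacing, origin=origin)
    return act_vol, mu_vol


def background_voi(
    spec: PhantomSpec,
    spacing: float,
    sphere_margin: float,
    hull_margin: float,
    shape=None,
) -> VoxelVolume:
    """Background VOI mask: hull eroded by ``hull_margin``, minus every
    sphere dilated by ``sphere_margin`` (all mm).

    Hull erosion uses a Euclidean distance transform on the voxelized hull;
    sphere exclusion is analytic.  Raises ``DegenerateGeometryError`` when
    the mask comes out empty.
    """
    if sphere_margin < 0 or hull_margin < 0:
        raise InvalidSpecError("margins must be >= 0")
    shape, origin = _grid_for(spec, spacing, shape)
    nx, ny, nz = shape
    xs = origin[0] + spacing * np.arange(nx)
    ys = origin[1] + spacing * np.arange(ny)
    zs = origin[2] + spacing * np.arange(nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    hull = _inside_hull(X, Y, Z, spec.hull_length_mm)
    if hull_margin > 0:
        dist_in = ndimage.distance_transform_edt(hull, sampling=spacing)
        mask = dist_in >= hull_margin
    else:
        mask = hull.copy()
    d = np.asarray(spec.sphere_diameters, dtype=float)
    for i in range(6):
        c = spec.sphere_centers[i]
        excl = (d[i] / 2.0 + sphere_margin) ** 2
        mask &= (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 > excl
    if not mask.any():
        raise DegenerateGeometryError("background VOI is empty for these margins")
    return VoxelVolume(values=mask, spacing=spacing, origin=origin)


def mask_volume_liters(mask: VoxelVolume) -> float:
    return float(mask.values.sum()) * mask.spacing**3 / 1e6
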
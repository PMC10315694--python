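"""Sphere-VOI placement, background peak search, and the SSR score.

The image-quality figure of merit is the signal-to-scatter peak ratio
(SSR): the mean of a spheric VOI over a sphere divided by the largest mean
of an equally sized spheric VOI anywhere in the background region.  An
SSR below 1 means the sphere is not defined above the scatter-induced
noise floor.  Sphere VOIs are placed semi-automatically: the VOI slides on
the voxel grid within a 20-mm search radius of the nominal (CT-derived)
position to maximize the enclosed total intensity, falling back to the
nominal position when no interior local maximum exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .phantom import VoxelVolume

__all__ = [
    "SphereVOI",
    "VoiStats",
    "sphere_kernel",
    "place_sphere_voi",
    "background_peak",
    "ssr",
    "normalized_count_rate",
    "compute_voi_stats",
]


class BoundaryError(ValueError):
    pass


class DegenerateMaskError(ValueError):
    pass


class UndefinedSSRError(ZeroDivisionError):
    pass


@dataclass
class SphereVOI:
    """A spheric VOI realized on the voxel grid."""

    center_mm: np.ndarray
    center_index: tuple[int, int, int]
    diameter: float
    voxel_indices: tuple[np.ndarray, np.ndarray, np.ndarray]
    has_local_max: bool

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices[0])


@dataclass
class VoiStats:
    """Per-sphere, per-reconstruction measurements."""

    max: float
    mean: float
    peak_background: float
    ssr: float
    has_local_max: bool
    normalized_max_rate: float | None = None  # counts/h per kBq/mL


def sphere_kernel(diameter_mm: float, spacing_mm: float) -> np.ndarray:
    """Boolean spheric kernel: voxel centers within diameter/2 of the middle."""
    r = diameter_mm / 2.0
    n = int(np.floor(r / spacing_mm))
    ax = np.arange(-n, n + 1) * spacing_mm
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    kern = X**2 + Y**2 + Z**2 <= r**2
    if not kern.any():  # diameter below one voxel: single-voxel kernel
        kern = np.ones((1, 1, 1), dtype=bool)
    return kern


def _kernel_offsets(kern: np.ndarray) -> np.ndarray:
    half = (np.asarray(kern.shape) - 1) // 2
    return np.argwhere(kern) - half


def place_sphere_voi(
    volume: VoxelVolume,
    nominal_center_mm,
    diameter_mm: float,
    search_radius_mm: float = 20.0,
) -> SphereVOI:
    """Optimal on-grid placement of a spheric VOI near a nominal position.

    The candidate maximizing the total enclosed intensity within
    ``search_radius_mm`` wins; ties are broken toward the nominal center,
    then by lexicographic voxel order.  ``has_local_max`` is True only when
    the maximizer is interior to the search ball (a full voxel step from
    its boundary) and strictly improves on the nominal position; otherwise
    the nominal position is kept.  Candidate totals are exact direct sums,
    so the result matches a brute-force search bit for bit.
    """
    vals = np.asarray(volume.values, dtype=np.float64)
    spacing = volume.spacing
    nom_idx = np.asarray(volume.index_of(nominal_center_mm))
    if np.any(nom_idx < 0) or np.any(nom_idx >= vals.shape):
        raise BoundaryError("nominal center outside the volume")

    kern = sphere_kernel(diameter_mm, spacing)
    k_off = _kernel_offsets(kern)

    n = int(np.floor(search_radius_mm / spacing))
    ax = np.arange(-n, n + 1)
    O = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)
    dist = np.linalg.norm(O * spacing, axis=1)
    O = O[dist <= search_radius_mm]
    dist = np.linalg.norm(O * spacing, axis=1)
    # deterministic candidate order: distance to nominal, then lexicographic
    order = np.lexsort((O[:, 2], O[:, 1], O[:, 0], np.round(dist, 9)))
    O, dist = O[order], dist[order]

    centers = nom_idx + O
    pts = centers[:, None, :] + k_off[None, :, :]
    if np.any(pts < 0) or np.any(pts >= np.asarray(vals.shape)):
        raise BoundaryError("candidate VOI extends outside the volume")
    totals = vals[pts[..., 0], pts[..., 1], pts[..., 2]].sum(axis=1)

    best = int(np.argmax(totals))  # first max in (distance, lex) order
    nominal_total = totals[np.all(O == 0, axis=1)][0]
    interior = dist[best] <= search_radius_mm - spacing
    improves = totals[best] > nominal_total
    if interior and improves:
        center_idx = tuple(int(v) for v in centers[best])
        has_max = True
    else:
        center_idx = tuple(int(v) for v in nom_idx)
        has_max = False
    vox = (np.asarray(center_idx) + k_off).T
    return SphereVOI(
        center_mm=np.asarray(center_idx) * spacing + volume.origin,
        center_index=center_idx,
        diameter=diameter_mm,
        voxel_indices=(vox[0], vox[1], vox[2]),
        has_local_max=has_max,
    )


def background_peak(
    volume: VoxelVolume,
    background_mask: np.ndarray,
    diameter_mm: float,
) -> tuple[float, tuple[int, int, int]]:
    """Largest spheric-kernel mean across the background region.

    Candidate centers are the voxels whose full kernel lies inside the
    mask (binary erosion of the mask by the kernel); the kernel mean field
    is the convolution of the volume with the normalized spheric kernel.
    """
    vals = np.asarray(volume.values, dtype=np.float64)
    mask = np.asarray(background_mask, dtype=bool)
    if mask.shape != vals.shape:
        raise DegenerateMaskError("mask and volume shapes differ")
    kern = sphere_kernel(diameter_mm, volume.spacing)
    admissible = ndimage.binary_erosion(mask, structure=kern, border_value=0)
    if not admissible.any():
        raise DegenerateMaskError("no admissible kernel position inside the mask")
    means = signal.fftconvolve(vals, kern[::-1, ::-1, ::-1] / kern.sum(), mode="same")
    masked = np.where(admissible, means, -np.inf)
    loc = np.unravel_index(int(np.argmax(masked)), masked.shape)
    return float(masked[loc]), tuple(int(v) for v in loc)


def ssr(
    volume: VoxelVolume,
    sphere_voi: SphereVOI,
    background_mask: np.ndarray,
) -> float:
    """Signal-to-scatter peak ratio: sphere VOI mean / volume-matched
    background peak.  Scale-invariant; raises when the peak is zero."""
    vals = np.asarray(volume.values)
    mean = float(vals[sphere_voi.voxel_indices].mean())
    peak, _ = background_peak(volume, background_mask, sphere_voi.diameter)
    # guard against fft residue masquerading as a positive peak
    if peak <= 1e-9 * max(float(np.abs(vals).max()), 1e-300):
        raise UndefinedSSRError("background peak is zero; SSR undefined")
    return mean / peak


def normalized_count_rate(
    max_counts: float, concentration_kbq_per_ml: float, duration_h: float
) -> float:
    """Counts per hour per kBq/mL: max / (concentration x duration)."""
    if concentration_kbq_per_ml <= 0 or duration_h <= 0:
        raise ValueError("concentration and duration must be > 0")
    return max_counts / (concentration_kbq_per_ml * duration_h)


def compute_voi_stats(
    volume: VoxelVolume,
    voi: SphereVOI,
    background_mask: np.ndarray,
    concentration_kbq_per_ml: float | None = None,
    duration_h: float | None = None,
) -> VoiStats:
    """Bundle max/mean/peak/SSR (and optionally the normalized max rate)."""
    vals = np.asarray(volume.values)[voi.voxel_indices]
    vmax = float(vals.max())
    vmean = float(vals.mean())
    peak, _ = background_peak(volume, background_mask, voi.diameter)
    rate = None
    if concentration_kbq_per_ml and duration_h:
        rate = normalized_count_rate(vmax, concentration_kbq_per_ml, duration_h)
    return VoiStats(
        max=vmax,
        mean=vmean,
        peak_background=peak,
        ssr=(vmean / peak) if peak > 0 else float("nan"),
        has_local_max=voi.has_local_max,
        normalized_max_rate=rate,
    )
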
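"""Threshold-based automatic ROI delineation (step 1 of the correction).

The delineator iterates a background-adapted fractional threshold

    T = B + q * (C_max - B)

where ``C_max`` is the maximum inside the current mask, ``B`` is the mean of
the matched background shell around the current mask, and ``q`` defaults to
0.39 — a published convention for this family of adaptive-threshold methods
that recovers sphere volumes accurately across the clinically relevant size
range.  The mask is the 26-connected component above T containing the seed.
Iteration stops when the mask reproduces itself.

The correction itself is delineation-agnostic: any externally supplied
:class:`RoiMask` (e.g. the true boundary of a simulated lesion) can be fed
to the correction directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid_io import PsfModel, VoxelGrid
from .shells import build_shells, exclude_neighbours

__all__ = ["RoiMask", "DelineationParams", "DelineationError", "delineate", "mask_statistics"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class DelineationError(RuntimeError):
    """No usable lesion mask could be produced (e.g. empty at every threshold)."""


@dataclass
class RoiMask:
    """Binary lesion mask on a grid with its summary statistics.

    ``v_roi_ml`` is the mask volume, ``c_mean``/``c_max`` the mean/maximum
    concentration inside the mask on the grid it was measured on.
    ``small_lesion`` flags equivalent-sphere diameters below twice the PSF
    FWHM, for which threshold delineation is unreliable.
    """

    mask: np.ndarray
    label: str = "roi"
    v_roi_ml: float = 0.0
    c_mean: float = 0.0
    c_max: float = 0.0
    cov: float = 0.0
    small_lesion: bool = False
    oscillated: bool = False
    n_iterations: int = 0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("RoiMask must be nonempty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def equivalent_diameter_mm(self) -> float:
        """Diameter of the sphere with the same volume as the mask."""
        return 2.0 * (3.0 * self.v_roi_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class DelineationParams:
    """Parameters of the iterative background-adapted threshold.

    ``denoise_fwhm_mm`` optionally pre-filters the image with a narrow
    Gaussian *for thresholding only* (the returned statistics are always
    measured on the original image).  On noisy data this stabilises the
    maximum-referenced threshold against single-voxel noise spikes; 0
    disables it.
    """

    threshold_fraction: float = 0.39
    max_iterations: int = 50
    seed_point: tuple[int, int, int] | None = None
    denoise_fwhm_mm: float = 0.0

    def __post_init__(self):
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.denoise_fwhm_mm < 0:
            raise ValueError("denoise_fwhm_mm must be non-negative")


def mask_statistics(grid: VoxelGrid, mask) -> tuple[float, float, float, float]:
    """Return ``(c_mean, c_max, v_roi_ml, cov)`` of the in-mask voxels.

    The coefficient of variation is the population sd over the mean.
    """
    m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    vals = grid.values[m]
    c_mean = float(vals.mean())
    c_max = float(vals.max())
    v_roi = m.sum() * grid.voxel_volume_ml
    cov = float(vals.std() / c_mean) if c_mean != 0 else float("inf")
    return c_mean, c_max, float(v_roi), cov


def as_roi(grid: VoxelGrid, mask: np.ndarray, label: str = "roi",
           psf: PsfModel | None = None) -> RoiMask:
    """Wrap a binary array as a :class:`RoiMask` with statistics from ``grid``."""
    c_mean, c_max, v_roi, cov = mask_statistics(grid, mask)
    roi = RoiMask(mask=np.asarray(mask, dtype=bool), label=label,
                  v_roi_ml=v_roi, c_mean=c_mean, c_max=c_max, cov=cov)
    if psf is not None:
        roi.small_lesion = roi.equivalent_diameter_mm() < 2.0 * psf.fwhm_mm
    return roi


def _component_containing(above: np.ndarray, anchor: tuple[int, int, int]) -> np.ndarray | None:
    """26-connected component of ``above`` containing ``anchor`` (None if absent).

    Interior holes are filled: a lesion includes its necrotic (cold) core,
    which is also why the correction provides a global-background fallback
    for spill-out voxels deep inside the ROI.
    """
    labels, n = ndimage.label(above, structure=_CONN26)
    lab = labels[anchor]
    if lab == 0:
        return None
    return ndimage.binary_fill_holes(labels == lab)


def _local_max_voxel(grid: VoxelGrid, seed: tuple[int, int, int], radius_mm: float):
    """Brightest voxel within ``radius_mm`` of the seed (lexicographic ties)."""
    lo, hi = [], []
    for a in range(3):
        r = max(1, int(round(radius_mm / grid.spacing[a])))
        lo.append(max(0, seed[a] - r))
        hi.append(min(grid.shape[a], seed[a] + r + 1))
    sub = grid.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    idx = np.unravel_index(int(np.argmax(sub)), sub.shape)
    return tuple(lo[a] + idx[a] for a in range(3))


def delineate(
    grid: VoxelGrid,
    params: DelineationParams,
    psf: PsfModel,
    other_rois=(),
) -> RoiMask:
    """Delineate one hot lesion by iterative background-adapted thresholding.

    Starting from the seed point (or the global maximum), the initial
    background estimate is the image median; thereafter the background is
    the mean of the matched background shell around the current mask, with
    neighbouring ROIs excluded.  Raises :class:`DelineationError` if the
    mask empties; an oscillating mask returns the last one with
    ``oscillated`` set.
    """
    if params.denoise_fwhm_mm > 0:
        from .grid_io import gaussian_smooth

        work = gaussian_smooth(grid, PsfModel(params.denoise_fwhm_mm))
    else:
        work = grid
    values = work.values
    if params.seed_point is not None:
        seed = tuple(int(i) for i in params.seed_point)
        if any(not 0 <= seed[a] < grid.shape[a] for a in range(3)):
            raise ValueError(f"seed point {seed} outside the grid")
        anchor = _local_max_voxel(work, seed, psf.fwhm_mm)
    else:
        anchor = tuple(int(i) for i in np.unravel_index(int(np.argmax(values)), grid.shape))

    q = params.threshold_fraction
    c_max = float(values[anchor])
    background = float(np.median(values))  # robust first guess; refined from shells
    mask = None
    seen: set[bytes] = set()
    oscillated = False
    n_iter = 0

    for n_iter in range(1, params.max_iterations + 1):
        threshold = background + q * (c_max - background)
        above = values >= threshold
        new_mask = _component_containing(above, anchor)
        if new_mask is None:
            raise DelineationError(
                f"no voxel above threshold {threshold:.4g} at the seed; "
                "lesion contrast may be too low"
            )
        if mask is not None and np.array_equal(new_mask, mask):
            mask = new_mask
            break
        key = np.packbits(new_mask).tobytes()
        if key in seen:
            oscillated = True
            mask = new_mask
            warnings.warn("delineation oscillated; returning the last mask", stacklevel=2)
            break
        seen.add(key)
        mask = new_mask

        c_max = float(values[mask].max())
        anchor = tuple(int(i) for i in np.unravel_index(
            int(np.argmax(np.where(mask, values, -np.inf))), grid.shape))
        shell_set = build_shells(mask, psf, grid.spacing)
        if other_rois:
            shell_set = exclude_neighbours(shell_set, other_rois, psf, grid.spacing)
        background = float(values[shell_set.background_mask].mean())

    roi = as_roi(grid, mask, psf=psf)
    roi.oscillated = oscillated
    roi.n_iterations = n_iter
    if roi.small_lesion:
        warnings.warn(
            f"lesion equivalent diameter {roi.equivalent_diameter_mm():.1f} mm "
            f"is below 2*FWHM = {2 * psf.fwhm_mm:.1f} mm; delineation unreliable",
            stacklevel=2,
        )
    return roi
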
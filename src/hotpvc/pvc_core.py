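"""Spill-out estimation and the partial-volume-corrected mean.

The corrected mean concentration of an ROI is

    C_mean_corr = (A_ROI + A_sp) / V_ROI,        A_ROI = C_mean * V_ROI,

where the spill-out activity is the background-corrected sum over the
spill-out shell,

    A_sp = V_vox * sum_{v in sp} (C(v) - B(v)).

LBPVC estimates B(v) locally for every spill-out voxel — the mean of
background-shell voxels within the search radius of v — so that spatially
varying backgrounds are handled per voxel.  GBPVC uses one global
background, the mean of the entire background shell, for every voxel.
Spill-out voxels with no background voxel in search range (e.g. inside a
necrotic core) fall back to the global background mean and are counted in
``n_fallback_voxels``.  A_sp is never clamped: net spill-in simply yields a
negative correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .delineation import RoiMask
from .grid_io import PsfModel, VoxelGrid
from .shells import ShellSet, build_shells, exclude_neighbours

__all__ = [
    "PvcResult",
    "local_background",
    "local_backgrounds",
    "global_background",
    "spillout_activity",
    "correct_mean",
    "run_lbpvc",
    "run_gbpvc",
]


@dataclass
class PvcResult:
    """All quantities entering and leaving the correction for one ROI."""

    method: str  # "lbpvc" | "gbpvc" | "none"
    c_mean_uncorrected: float
    c_mean_corrected: float
    a_roi: float
    a_sp: float
    v_roi_ml: float
    global_background: float
    n_fallback_voxels: int
    n_spillout_voxels: int
    assumed_fwhm_mm: float
    shells_truncated: bool = False
    background_map: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "background_map"}
        return d


def _sphere_footprint(radius_mm: float, spacing) -> np.ndarray:
    """Boolean kernel of voxel offsets whose centre distance is <= radius_mm."""
    half = [int(np.floor(radius_mm / s + 1e-9)) for s in spacing]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    d2 = sum(g**2 for g in grids)
    return d2 <= radius_mm**2 + 1e-6


def global_background(grid: VoxelGrid, shells: ShellSet) -> float:
    """Mean concentration over the entire background shell."""
    bg = shells.background_mask
    if not bg.any():
        raise ValueError("background region is empty")
    return float(grid.values[bg].mean())


def local_backgrounds(
    grid: VoxelGrid, shells: ShellSet
) -> tuple[np.ndarray, int]:
    """Per-voxel local backgrounds B(v) on the full grid.

    For every voxel, the mean of background-shell voxels within the shell
    set's search radius (centre-to-centre distance); voxels with none in
    range carry the global background mean.  Returns the B map and the
    number of *spill-out* voxels that needed the global fallback.

    Implemented as two correlations with a spherical footprint (sum and
    count of in-range background voxels), which is exact and fast.
    """
    bg = shells.background_mask
    gmean = global_background(grid, shells)
    kernel = _sphere_footprint(shells.search_radius_mm, grid.spacing).astype(np.float64)
    counts = ndimage.correlate(bg.astype(np.float64), kernel, mode="constant", cval=0.0)
    sums = ndimage.correlate(
        np.where(bg, grid.values, 0.0), kernel, mode="constant", cval=0.0
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        b_map = np.where(counts > 0.5, sums / np.maximum(counts, 1e-300), gmean)
    n_fallback = int(np.count_nonzero(shells.spillout_mask & (counts < 0.5)))
    return b_map, n_fallback


def local_background(
    voxel: tuple[int, int, int], grid: VoxelGrid, shells: ShellSet
) -> tuple[float, bool]:
    """B(v) for a single spill-out voxel; ``(value, used_global_fallback)``.

    Direct (non-convolutional) evaluation, used for spot checks and small
    problems; agrees with :func:`local_backgrounds` exactly.
    """
    if not shells.spillout_mask[voxel]:
        raise ValueError("voxel is not in the spill-out region")
    coords = np.argwhere(shells.background_mask)
    deltas = (coords - np.asarray(voxel)) * np.asarray(grid.spacing)
    in_range = np.einsum("ij,ij->i", deltas, deltas) <= shells.search_radius_mm**2 + 1e-6
    if not in_range.any():
        return global_background(grid, shells), True
    sel = coords[in_range]
    return float(grid.values[sel[:, 0], sel[:, 1], sel[:, 2]].mean()), False


def spillout_activity(
    grid: VoxelGrid, shells: ShellSet, backgrounds: np.ndarray
) -> float:
    """A_sp = V_vox * sum over spill-out voxels of (C(v) - B(v)).

    ``backgrounds`` is a full-grid B map (only spill-out entries are read).
    May be negative; the sign is propagated.  Uses compensated summation so
    the result is independent of voxel order.
    """
    if backgrounds.shape != grid.shape:
        raise ValueError("background map shape does not match the grid")
    sp = shells.spillout_mask
    diffs = grid.values[sp] - backgrounds[sp]
    return grid.voxel_volume_ml * math.fsum(diffs.tolist())


def correct_mean(
    roi: RoiMask,
    a_sp: float,
    *,
    method: str = "lbpvc",
    global_bg: float = float("nan"),
    n_fallback: int = 0,
    n_spill: int = 0,
    assumed_fwhm_mm: float = float("nan"),
    truncated: bool = False,
    background_map: np.ndarray | None = None,
) -> PvcResult:
    """Apply C_mean_corr = (A_ROI + A_sp) / V_ROI and package the result."""
    if not roi.v_roi_ml > 0:
        raise ValueError("ROI volume must be positive")
    a_roi = roi.c_mean * roi.v_roi_ml
    corrected = (a_roi + a_sp) / roi.v_roi_ml
    return PvcResult(
        method=method,
        c_mean_uncorrected=roi.c_mean,
        c_mean_corrected=corrected,
        a_roi=a_roi,
        a_sp=a_sp,
        v_roi_ml=roi.v_roi_ml,
        global_background=global_bg,
        n_fallback_voxels=n_fallback,
        n_spillout_voxels=n_spill,
        assumed_fwhm_mm=assumed_fwhm_mm,
        shells_truncated=truncated,
        background_map=background_map,
    )


def _run(
    grid: VoxelGrid,
    roi: RoiMask,
    other_rois,
    psf: PsfModel,
    method: str,
    keep_background_map: bool,
) -> PvcResult:
    shell_set = build_shells(roi.mask, psf, grid.spacing)
    if other_rois:
        shell_set = exclude_neighbours(shell_set, other_rois, psf, grid.spacing)
    gmean = global_background(grid, shell_set)
    if method == "lbpvc":
        b_map, n_fallback = local_backgrounds(grid, shell_set)
    elif method == "gbpvc":
        b_map = np.full(grid.shape, gmean)
        n_fallback = 0
    else:
        raise ValueError(f"unknown method {method!r}")
    a_sp = spillout_activity(grid, shell_set, b_map)
    if a_sp < 0:
        warnings.warn(
            f"net spill-out activity is negative ({a_sp:.4g}); "
            "spill-in exceeds spill-out for this ROI",
            stacklevel=3,
        )
    return correct_mean(
        roi,
        a_sp,
        method=method,
        global_bg=gmean,
        n_fallback=n_fallback,
        n_spill=int(shell_set.spillout_mask.sum()),
        assumed_fwhm_mm=psf.fwhm_mm,
        truncated=shell_set.truncated,
        background_map=b_map if keep_background_map else None,
    )


def run_lbpvc(
    grid: VoxelGrid,
    roi: RoiMask,
    other_rois=(),
    psf: PsfModel = PsfModel(8.0),
    keep_background_map: bool = False,
) -> PvcResult:
    """Local-background partial volume correction for one ROI."""
    return _run(grid, roi, other_rois, psf, "lbpvc", keep_background_map)


def run_gbpvc(
    grid: VoxelGrid,
    roi: RoiMask,
    other_rois=(),
    psf: PsfModel = PsfModel(8.0),
    keep_background_map: bool = False,
) -> PvcResult:
    """Global-background variant: B(v) is the background-shell mean everywhere."""
    return _run(grid, roi, other_rois, psf, "gbpvc", keep_background_map)
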
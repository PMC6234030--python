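"""3D synapse density mapping and glomerulus territory segmentation.

Glomerular borders show up in whole-lobe synapse point clouds as local
rarefactions of synapse density.  This module bins T-bar positions into a
regular 3D grid (default 1 µm bins), smooths with a Gaussian kernel
(default σ = 2 bins), thresholds the smoothed density at a quantile of its
nonzero values, and labels the connected components (26-neighbour) as
glomerulus-like regions.  Regions are numbered in descending order of the
raw point count they contain; small regions are merged to background.

Voxelization is half-open: a point p falls in voxel i iff
origin + i·bin <= p < origin + (i+1)·bin, per axis.  The grid is padded so
that Gaussian smoothing (reflect boundary) conserves total mass exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import watershed

__all__ = [
    "DensityGrid",
    "RegionLabel",
    "density_map",
    "segment_regions",
    "assign_to_roi",
]

logger = logging.getLogger(__name__)


@dataclass
class DensityGrid:
    """Binned 3D synapse density.

    ``counts`` holds raw per-voxel point counts (their sum equals the number
    of points inside the grid extent); ``density`` the Gaussian-smoothed
    field on the same grid (equal to ``counts`` when σ = 0).
    """

    origin: np.ndarray  # nm, lower corner of voxel (0,0,0)
    bin_size: float  # nm per voxel side
    counts: np.ndarray  # raw histogram
    density: np.ndarray  # smoothed
    sigma_bins: float

    def voxel_of(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel index per point (may fall outside the grid)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor((points - self.origin) / self.bin_size).astype(int)

    def inside(self, voxels: np.ndarray) -> np.ndarray:
        shape = np.array(self.counts.shape)
        return ((voxels >= 0) & (voxels < shape)).all(axis=1)


@dataclass
class RegionLabel:
    """Labelled glomerulus-like territories on a density grid.

    ``labels`` assigns every voxel a region id (0 = background); labels are
    contiguous integers 1..K ordered by descending contained point count.
    ``regions`` summarizes each region (voxel count, point count, centroid
    in nm).  Carries the grid geometry so points can be assigned to regions.
    """

    labels: np.ndarray
    regions: pd.DataFrame
    origin: np.ndarray
    bin_size: float

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())


def density_map(
    points: np.ndarray,
    bin_size_nm: float = 1000.0,
    smoothing_sigma_bins: float = 2.0,
) -> DensityGrid:
    """Histogram a point cloud into voxels and smooth.

    The grid covers the bounding box of the points plus a margin of
    ``ceil(3σ) + 1`` bins per side, so raw histogramming conserves the
    point count and reflect-mode Gaussian smoothing conserves total mass to
    floating-point accuracy.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("empty point cloud")
    if points.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if bin_size_nm <= 0:
        raise ValueError("bin_size_nm must be positive")
    if smoothing_sigma_bins < 0:
        raise ValueError("smoothing sigma must be non-negative")

    pad = int(np.ceil(3 * smoothing_sigma_bins)) + 1
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    origin = lo - pad * bin_size_nm
    n_bins = np.ceil((hi - origin) / bin_size_nm).astype(int) + 1 + pad
    edges = [
        origin[a] + bin_size_nm * np.arange(n_bins[a] + 1) for a in range(3)
    ]
    counts, _ = np.histogramdd(points, bins=edges)
    if smoothing_sigma_bins > 0:
        density = ndimage.gaussian_filter(
            counts, sigma=smoothing_sigma_bins, mode="reflect"
        )
    else:
        density = counts.copy()
    return DensityGrid(
        origin=origin,
        bin_size=float(bin_size_nm),
        counts=counts,
        density=density,
        sigma_bins=float(smoothing_sigma_bins),
    )


_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


def segment_regions(
    grid: DensityGrid,
    threshold_mode: str = "quantile",
    quantile: float = 0.6,
    threshold: float | None = None,
    capture_quantile: float = 0.05,
    min_region_points: int = 30,
) -> RegionLabel:
    """Segment glomerulus-like territories from a smoothed density grid.

    Region *cores* are the 26-connected components of voxels whose smoothed
    density reaches the core threshold — by default the ``quantile``-th
    quantile of the smoothed density over voxels that contain at least one
    raw point (restricting to occupied voxels keeps the smoothing halo of
    near-zero values from dragging the quantile down).  Each core is then
    extended outward by a watershed on the inverted density, restricted to
    voxels above the lower ``capture_quantile`` threshold, so that region
    boundaries fall at local density rarefactions while each region still
    captures the bulk of its glomerulus' points.

    Components containing fewer than ``min_region_points`` raw points are
    merged to background.  Labels are assigned 1..K by descending contained
    point count (ties by lowest voxel index), so the labelling is
    deterministic and invariant to point order.
    """
    occupied = grid.density[grid.counts > 0]
    if threshold_mode == "quantile":
        if occupied.size == 0:
            logger.warning("all-background density grid; no regions")
            return _empty_labels(grid)
        thr = float(np.quantile(occupied, quantile))
    elif threshold_mode == "absolute":
        if threshold is None:
            raise ValueError("absolute threshold_mode requires threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")

    core_mask = grid.density >= thr
    if not core_mask.any():
        logger.warning("threshold %.3g left no foreground voxels", thr)
        return _empty_labels(grid)

    cores, n_raw = ndimage.label(core_mask, structure=_STRUCTURE_26)
    if n_raw == 0:
        return _empty_labels(grid)

    if capture_quantile is not None and occupied.size:
        low = float(np.quantile(occupied, capture_quantile))
        capture_mask = grid.density >= min(low, thr)
        raw_labels = watershed(
            -grid.density,
            markers=cores,
            mask=capture_mask,
            connectivity=_STRUCTURE_26,
        )
    else:
        raw_labels = cores

    point_counts = ndimage.sum_labels(
        grid.counts, raw_labels, index=np.arange(1, n_raw + 1)
    )
    keep = [
        (int(point_counts[k - 1]), k)
        for k in range(1, n_raw + 1)
        if point_counts[k - 1] >= min_region_points
    ]
    # descending point count; ties broken by first-occurring voxel
    first_voxel = {}
    flat = raw_labels.ravel()
    for pos in range(flat.size):
        lab = flat[pos]
        if lab and lab not in first_voxel:
            first_voxel[lab] = pos
    keep.sort(key=lambda t: (-t[0], first_voxel[t[1]]))

    labels = np.zeros_like(raw_labels)
    rows = []
    for new_id, (n_points, old_id) in enumerate(keep, start=1):
        region_mask = raw_labels == old_id
        labels[region_mask] = new_id
        voxel_idx = np.argwhere(region_mask)
        weights = grid.counts[region_mask]
        if weights.sum() > 0:
            centroid_vox = (voxel_idx * weights[:, None]).sum(axis=0) / weights.sum()
        else:
            centroid_vox = voxel_idx.mean(axis=0)
        centroid_nm = grid.origin + (centroid_vox + 0.5) * grid.bin_size
        rows.append(
            {
                "label": new_id,
                "n_voxels": int(region_mask.sum()),
                "n_points": int(n_points),
                "centroid_x_nm": centroid_nm[0],
                "centroid_y_nm": centroid_nm[1],
                "centroid_z_nm": centroid_nm[2],
            }
        )
    if not rows:
        logger.warning("all candidate regions below min_region_points")
    return RegionLabel(
        labels=labels,
        regions=pd.DataFrame(
            rows,
            columns=[
                "label",
                "n_voxels",
                "n_points",
                "centroid_x_nm",
                "centroid_y_nm",
                "centroid_z_nm",
            ],
        ),
        origin=grid.origin,
        bin_size=grid.bin_size,
    )


def _empty_labels(grid: DensityGrid) -> RegionLabel:
    return RegionLabel(
        labels=np.zeros(grid.counts.shape, dtype=np.int32),
        regions=pd.DataFrame(
            columns=[
                "label",
                "n_voxels",
                "n_points",
                "centroid_x_nm",
                "centroid_y_nm",
                "centroid_z_nm",
            ]
        ),
        origin=grid.origin,
        bin_size=grid.bin_size,
    )


def assign_to_roi(
    points: np.ndarray, labels: RegionLabel, target_region: int
) -> np.ndarray:
    """Boolean mask of the points whose voxel carries ``target_region``.

    A point is inside the ROI iff the voxel containing it (half-open
    binning) is labelled with the target region; points outside the grid
    extent are excluded with a warning.
    """
    if target_region < 1 or target_region > labels.labels.max():
        raise ValueError(f"unknown region id {target_region}")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    voxels = np.floor((points - labels.origin) / labels.bin_size).astype(int)
    shape = np.array(labels.labels.shape)
    inside = ((voxels >= 0) & (voxels < shape)).all(axis=1)
    if not inside.all():
        logger.warning(
            "%d points fall outside the label grid extent", int((~inside).sum())
        )
    mask = np.zeros(len(points), dtype=bool)
    idx = voxels[inside]
    mask[inside] = labels.labels[idx[:, 0], idx[:, 1], idx[:, 2]] == target_region
    return mask
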
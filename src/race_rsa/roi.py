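"""ROI definition on statistical maps by thresholded flood fill.

Face-selective regions are defined on a z-statistic contrast map (e.g.
faces > scenes): the peak voxel is located, then a flood fill grows a
cluster of spatially contiguous voxels above a lower threshold
(z > 2.3 by default) up to a target size (500 voxels).  If fewer
suprathreshold voxels are reachable from the peak, the region is defined by
the largest size rounded down to the nearest 100, dropping the last-added
(lowest-z) voxels so the cluster stays connected.

Growth order is greedy highest-z-first over the connected frontier with
ties broken by lowest linear index, which makes the result deterministic.
Connectivity is face-adjacency (6 neighbours) by default; 18 and 26 are
available.  Voxel indices are 0-based; world coordinates in mm come from
the NIfTI affine.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.affines import apply_affine

from .errors import DataError

__all__ = [
    "StatMap",
    "ROIConfig",
    "ROIMask",
    "find_peak",
    "flood_fill_roi",
    "reachable_suprathreshold",
    "peak_report",
]


@dataclass
class StatMap:
    """A 3-D statistical volume (z values) with a voxel-to-world-mm affine."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3:
            raise DataError(f"stat map must be 3-D, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise DataError("stat map contains non-finite values")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise DataError("affine must be an invertible 4x4 matrix")

    @classmethod
    def from_nifti(cls, path) -> "StatMap":
        img = nib.load(str(path))
        return cls(values=np.asarray(img.get_fdata(), dtype=np.float64), affine=img.affine)

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.values, self.affine), str(path))


@dataclass
class ROIConfig:
    target_size: int = 500
    z_min: float = 2.3
    fallback_rounding: int = 100
    connectivity: int = 6

    def __post_init__(self) -> None:
        if self.target_size <= 0:
            raise DataError("target_size must be positive")
        if self.fallback_rounding <= 0:
            raise DataError("fallback_rounding must be positive")
        if self.connectivity not in (6, 18, 26):
            raise DataError("connectivity must be 6, 18 or 26")


@dataclass
class ROIMask:
    mask: np.ndarray
    peak_index: tuple
    peak_world_mm: np.ndarray
    n_voxels: int
    affine: np.ndarray

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), self.affine), str(path))

    @classmethod
    def from_nifti(cls, path, peak_index: tuple | None = None) -> "ROIMask":
        img = nib.load(str(path))
        mask = np.asarray(img.get_fdata()) > 0.5
        if peak_index is None:
            nz = np.argwhere(mask)
            if nz.size == 0:
                raise DataError(f"mask {path} is empty")
            peak_index = tuple(int(v) for v in nz[0])
        return cls(
            mask=mask,
            peak_index=tuple(peak_index),
            peak_world_mm=np.asarray(apply_affine(img.affine, peak_index), dtype=float),
            n_voxels=int(mask.sum()),
            affine=np.asarray(img.affine),
        )


def _offsets(connectivity: int) -> list:
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    return [
        off
        for off in itertools.product((-1, 0, 1), repeat=3)
        if 0 < sum(abs(o) for o in off) <= order
    ]


def find_peak(statmap: StatMap, search_mask: np.ndarray | None = None):
    """Peak voxel (highest z); ties broken by lowest linear index.

    Returns ``(index_tuple, z_value)``.  ``search_mask`` restricts the
    search to a boolean subvolume.
    """
    z = statmap.values
    if search_mask is not None:
        search_mask = np.asarray(search_mask, dtype=bool)
        if search_mask.shape != z.shape:
            raise DataError("search mask shape does not match map")
        if not search_mask.any():
            raise DataError("empty search region")
        z = np.where(search_mask, z, -np.inf)
    lin = int(np.argmax(z))  # argmax returns the first (lowest linear index) maximum
    idx = np.unravel_index(lin, z.shape)
    return tuple(int(i) for i in idx), float(statmap.values[idx])


def flood_fill_roi(statmap: StatMap, peak, cfg: ROIConfig | None = None) -> ROIMask:
    """Grow a connected suprathreshold cluster of cfg.target_size voxels from the peak.

    Greedy growth: the suprathreshold neighbour of the current region with
    the highest z is added next, until the target size is reached or no
    suprathreshold neighbour remains.  If the reachable set is smaller than
    the target, the region size is rounded down to the nearest
    ``fallback_rounding`` by dropping the last-added voxels (which keeps the
    region connected).  Raises if the peak is below threshold or the
    reachable set rounds down to zero.
    """
    cfg = cfg or ROIConfig()
    z = statmap.values
    peak = tuple(int(i) for i in peak)
    if not z[peak] > cfg.z_min:
        raise DataError(
            f"peak z = {z[peak]:.3f} at {peak} does not exceed threshold {cfg.z_min}"
        )
    shape = z.shape
    offs = _offsets(cfg.connectivity)
    queued = np.zeros(shape, dtype=bool)
    heap: list = []

    def push(idx):
        if not queued[idx] and z[idx] > cfg.z_min:
            queued[idx] = True
            heapq.heappush(heap, (-z[idx], int(np.ravel_multi_index(idx, shape))))

    push(peak)
    accepted: list = []
    while heap and len(accepted) < cfg.target_size:
        _, lin = heapq.heappop(heap)
        idx = tuple(int(i) for i in np.unravel_index(lin, shape))
        accepted.append(idx)
        for off in offs:
            nb = (idx[0] + off[0], idx[1] + off[1], idx[2] + off[2])
            if 0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1] and 0 <= nb[2] < shape[2]:
                push(nb)
    if len(accepted) < cfg.target_size:
        k = (len(accepted) // cfg.fallback_rounding) * cfg.fallback_rounding
        if k == 0:
            raise DataError(
                f"only {len(accepted)} suprathreshold voxels reachable from {peak}; "
                f"cannot form an ROI at rounding {cfg.fallback_rounding}"
            )
        accepted = accepted[:k]
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(np.array(accepted).T)] = True
    return ROIMask(
        mask=mask,
        peak_index=peak,
        peak_world_mm=np.asarray(apply_affine(statmap.affine, peak), dtype=float),
        n_voxels=len(accepted),
        affine=statmap.affine,
    )


def reachable_suprathreshold(
    statmap: StatMap, peak, z_min: float = 2.3, connectivity: int = 6
) -> int:
    """Size of the full connected suprathreshold component containing the peak."""
    cfg = ROIConfig(target_size=statmap.values.size, z_min=z_min,
                    fallback_rounding=1, connectivity=connectivity)
    return flood_fill_roi(statmap, peak, cfg).n_voxels


def peak_report(statmap: StatMap, rois: dict) -> pd.DataFrame:
    """Tidy peak table (ROI, hemisphere, world mm coordinates, size, peak z)."""
    rows = []
    for name, roi in rois.items():
        x, y, z_mm = roi.peak_world_mm
        rows.append(
            dict(roi=name, hemisphere="left" if x < 0 else "right",
                 x=float(x), y=float(y), z=float(z_mm),
                 voxels=roi.n_voxels,
                 peak_z=float(statmap.values[roi.peak_index]))
        )
    return pd.DataFrame(rows)
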
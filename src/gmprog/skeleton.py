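"""Cortical-skeleton construction and per-subject sampling.

The skeleton is the one-voxel-thick medial surface through the center of
the cortical grey-matter plate of the cohort-mean map. Sampling subjects
there reduces partial-volume effects at the plate's edges.

The default extraction is a ridge criterion on graded maps: after Gaussian
smoothing, a voxel is kept if it lies in the thresholded grey-matter mask
and is a local maximum of the smoothed map along the direction of dominant
(most negative) curvature — the Hessian eigenvector of the smallest
eigenvalue. A morphological-thinning fallback exists for degenerate maps
where the ridge is flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ShapeError, SpecValidationError
from .volume_io import VolumeImage, check_grids

METHODS = ("ridge", "thinning")


@dataclass
class SkeletonModel:
    """The cohort-mean map together with its extracted skeleton mask."""

    mean_map: VolumeImage
    skeleton_mask: np.ndarray  # 3D bool, same grid as mean_map
    gm_threshold: float
    smoothing_sigma_mm: float
    method: str = "ridge"
    _indices: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_voxels(self) -> int:
        return int(self.skeleton_mask.sum())

    @property
    def indices(self) -> np.ndarray:
        """(n, 3) voxel indices of skeleton voxels, lexicographic order."""
        if self._indices is None:
            self._indices = np.argwhere(self.skeleton_mask)
        return self._indices

    def thinness_fraction(self) -> float:
        """Fraction of skeleton voxels whose 3x3x3 neighborhood holds <= 9."""
        counts = ndimage.convolve(
            self.skeleton_mask.astype(np.int32), np.ones((3, 3, 3), dtype=np.int32), mode="constant"
        )
        return float(np.mean(counts[self.skeleton_mask] <= 9)) if self.n_voxels else 1.0

    def embed(self, values: np.ndarray) -> np.ndarray:
        """Scatter a per-skeleton-voxel vector back into a 3D grid (0 elsewhere)."""
        if values.shape != (self.n_voxels,):
            raise ShapeError(f"expected vector of length {self.n_voxels}, got {values.shape}")
        grid = np.zeros(self.skeleton_mask.shape, dtype=float)
        grid[self.skeleton_mask] = values
        return grid


def mean_image(volumes: Sequence[VolumeImage]) -> VolumeImage:
    """Voxelwise arithmetic mean over all scans (controls and both patient
    timepoints enter equally)."""
    if len(volumes) == 0:
        raise ShapeError("mean_image needs at least one volume")
    check_grids(volumes)
    acc = np.zeros(volumes[0].shape)
    for v in volumes:
        acc += v.data
    acc /= len(volumes)
    return VolumeImage(acc, voxel_size_mm=volumes[0].voxel_size_mm, affine=volumes[0].affine)


def _hessian_ridge_mask(smoothed: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Voxels of ``mask`` that are local maxima of ``smoothed`` along the
    dominant-curvature direction (unit step, trilinear interpolation)."""
    grads = np.gradient(smoothed)
    hess = np.empty(smoothed.shape + (3, 3))
    for i in range(3):
        gg = np.gradient(grads[i])
        for j in range(3):
            hess[..., i, j] = gg[j]
    idx = np.argwhere(mask)
    h = hess[mask]  # (n, 3, 3)
    h = 0.5 * (h + np.transpose(h, (0, 2, 1)))  # enforce symmetry
    eigvals, eigvecs = np.linalg.eigh(h)
    # eigh sorts ascending: column 0 is the most negative curvature direction
    ridge_dir = eigvecs[..., 0]
    negative_curv = eigvals[:, 0] < 0

    pts = idx.astype(float)
    up = (pts + ridge_dir).T
    down = (pts - ridge_dir).T
    center = smoothed[mask]
    v_up = ndimage.map_coordinates(smoothed, up, order=1, mode="nearest")
    v_down = ndimage.map_coordinates(smoothed, down, order=1, mode="nearest")
    keep = negative_curv & (center >= v_up) & (center >= v_down)

    out = np.zeros_like(mask)
    out[tuple(idx[keep].T)] = True
    return out


def skeletonize(
    mean_map: VolumeImage,
    gm_threshold: float = 0.2,
    smoothing_sigma_mm: float = 2.0,
    method: str = "ridge",
) -> SkeletonModel:
    """Extract the medial-surface skeleton of the cohort-mean GM map.

    Parameters
    ----------
    gm_threshold : float in (0, 1)
        Voxels of the (unsmoothed) mean map below this GM value are never
        part of the skeleton.
    smoothing_sigma_mm : float
        Gaussian smoothing applied before ridge detection, in mm.
    method : {"ridge", "thinning"}
        Ridge criterion (default) or morphological thinning fallback.
    """
    if not 0 < gm_threshold < 1:
        raise SpecValidationError("gm_threshold", "must lie in (0, 1)")
    if smoothing_sigma_mm < 0:
        raise SpecValidationError("smoothing_sigma_mm", "must be non-negative")
    if method not in METHODS:
        raise SpecValidationError("method", f"must be one of {METHODS}")

    mask = mean_map.data >= gm_threshold
    if not mask.any():
        raise DegenerateInputError(
            f"no voxel of the mean map reaches gm_threshold={gm_threshold}"
        )

    sigma_vox = [smoothing_sigma_mm / vs for vs in mean_map.voxel_size_mm]
    smoothed = ndimage.gaussian_filter(mean_map.data, sigma_vox) if smoothing_sigma_mm else mean_map.data

    if method == "ridge":
        skel = _hessian_ridge_mask(smoothed, mask)
        if not skel.any():
            raise DegenerateInputError("ridge criterion produced an empty skeleton")
    else:
        from skimage.morphology import skeletonize as _thin

        skel = _thin(mask) & mask
        if not skel.any():
            raise DegenerateInputError("thinning produced an empty skeleton")

    return SkeletonModel(
        mean_map=mean_map,
        skeleton_mask=skel,
        gm_threshold=gm_threshold,
        smoothing_sigma_mm=smoothing_sigma_mm,
        method=method,
    )


def sample_on_skeleton(volume: VolumeImage, model: SkeletonModel) -> np.ndarray:
    """Per-skeleton-voxel GMV values, in the model's fixed lexicographic
    voxel order (shared across all subjects)."""
    if volume.shape != model.skeleton_mask.shape:
        raise ShapeError(
            f"volume grid {volume.shape} does not match skeleton grid {model.skeleton_mask.shape}"
        )
    return volume.data[model.skeleton_mask]


def sample_matrix(volumes: Sequence[VolumeImage], model: SkeletonModel) -> np.ndarray:
    """(n_scans, n_skeleton_voxels) matrix of sampled GMV values."""
    return np.stack([sample_on_skeleton(v, model) for v in volumes])
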
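"""Gray-matter analysis mask from per-subject tissue probability maps."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = ["GrayMatterMask", "build_graymatter_mask", "fwhm_to_sigma"]

#: FWHM of a Gaussian equals sigma * sqrt(8 ln 2).
_FWHM_FACTOR = math.sqrt(8.0 * math.log(2.0))


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Gaussian sigma in voxel units for a kernel FWHM given in mm."""
    return fwhm_mm / (_FWHM_FACTOR * voxel_size_mm)


@dataclass(frozen=True)
class GrayMatterMask:
    mask: np.ndarray            # 3D bool, functional grid
    threshold: float
    fwhm_mm: float
    voxel_size_mm: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def build_graymatter_mask(
    probability_maps: Sequence[np.ndarray],
    fwhm_mm: float = 8.0,
    threshold: float = 0.3,
    voxel_size_mm: float = 3.0,
) -> GrayMatterMask:
    """Average subject gray-matter probability maps, smooth, threshold.

    The subject maps are averaged voxelwise, smoothed with a Gaussian
    kernel of the given FWHM, and voxels strictly above ``threshold``
    are retained.  An empty result is an error (wrong grid or threshold).
    """
    maps = [np.asarray(m, dtype=float) for m in probability_maps]
    if not maps:
        raise ValueError("no probability maps given")
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise ValueError("probability maps must share one grid")
        if np.nanmin(m) < 0 or np.nanmax(m) > 1:
            raise ValueError("probability values must lie in [0, 1]")
    avg = np.mean(maps, axis=0)
    if fwhm_mm > 0:
        avg = ndimage.gaussian_filter(avg, fwhm_to_sigma(fwhm_mm, voxel_size_mm))
    mask = avg > threshold
    if not mask.any():
        raise ValueError(
            f"gray-matter mask empty at threshold {threshold} (max smoothed "
            f"probability {avg.max():.3f})"
        )
    return GrayMatterMask(mask, threshold, fwhm_mm, voxel_size_mm)
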
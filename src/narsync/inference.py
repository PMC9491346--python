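"""One-sample group inference by sign-flip permutation.

Subject contrast maps are tested against zero with a one-sample t
statistic whose null distribution is built by randomly negating each
subject's map (valid under the exchangeability-free symmetry assumption
that each subject's contrast is sign-symmetric under the null).  The
identity flip is always included, so p-values are never 0 and never
below 1/n_permutations.  Cluster-extent FWE correction thresholds the
observed and every permuted statistic map at the permutation-null
quantile corresponding to the height-defining alpha and compares each
observed cluster's size with the permutation distribution of the
maximum suprathreshold cluster size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PermutationResult",
    "sign_flip_test",
    "cluster_correction",
    "roi_summary",
    "sign_flip_ttest_1samp",
]


def _one_sample_t(maps: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """t statistic per column for every flip pattern.

    ``maps`` is (n_subjects, n_voxels); ``flips`` is (n_perm, n_subjects)
    of +-1.  The per-voxel sum of squares is flip-invariant, so the whole
    family of permuted t maps reduces to one matrix product.
    """
    n = maps.shape[0]
    mean = flips @ maps / n
    ss = np.einsum("ij,ij->j", maps, maps)
    var = (ss[None, :] - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    # zero-variance voxels: all values identical; t is +-inf or 0
    t[np.isnan(t)] = 0.0
    return t


def _make_flips(n_perm: int, n_subj: int, rng: np.random.Generator) -> np.ndarray:
    flips = rng.choice(np.array([-1.0, 1.0]), size=(n_perm, n_subj))
    flips[0] = 1.0  # identity permutation always in the null
    return flips


@dataclass
class PermutationResult:
    """Voxel-level sign-flip test output plus permutation machinery."""

    stat: np.ndarray                       # observed t per in-analysis voxel
    voxel_p: np.ndarray                    # permutation p per voxel
    n_permutations: int
    seed: int | None
    mask: np.ndarray | None                # 3D bool geometry, if supplied
    maps: np.ndarray = field(repr=False)   # (n_subjects, n_voxels), valid voxels
    flips: np.ndarray = field(repr=False)  # (n_perm, n_subjects) of +-1
    valid: np.ndarray = field(repr=False)  # bool, voxels kept in inference
    dropped_voxels: int = 0
    cluster_table: pd.DataFrame | None = None
    null_max_cluster: np.ndarray | None = None

    def stat_volume(self) -> np.ndarray:
        """Observed t embedded in the 3D mask grid (NaN outside)."""
        if self.mask is None:
            raise ValueError("no 3D geometry attached")
        vol = np.full(self.mask.shape, np.nan)
        idx = np.flatnonzero(self.mask.ravel())[self.valid]
        vol.ravel()[idx] = self.stat
        return vol


def sign_flip_test(
    maps: np.ndarray | Sequence[np.ndarray],
    n_permutations: int = 5000,
    seed: int | None = None,
    mask: np.ndarray | None = None,
) -> PermutationResult:
    """Voxelwise one-sample sign-flip permutation test (one-sided, greater).

    Parameters
    ----------
    maps:
        Per-subject contrast maps, stacked as ``(n_subjects, n_voxels)``
        (or a sequence of 1D maps).  Voxels that are NaN in any subject
        are dropped from inference and counted in ``dropped_voxels``.
    n_permutations:
        Number of sign-flip patterns, identity included.  At least 1000.
    mask:
        Optional 3D boolean grid giving the voxels' geometry, required
        later for cluster correction.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2:
        raise ValueError("maps must be (n_subjects, n_voxels)")
    n_subj = maps.shape[0]
    if n_subj < 6:
        raise ValueError("need at least 6 subjects for sign-flip inference")
    if n_permutations < 1000:
        raise ValueError("need at least 1000 permutations")
    valid = ~np.isnan(maps).any(axis=0)
    dropped = int((~valid).sum())
    maps_v = np.ascontiguousarray(maps[:, valid])
    rng = np.random.default_rng(seed)
    flips = _make_flips(n_permutations, n_subj, rng)
    t_null = _one_sample_t(maps_v, flips)
    t_obs = t_null[0]
    voxel_p = (t_null >= t_obs[None, :]).mean(axis=0)
    return PermutationResult(
        stat=t_obs,
        voxel_p=voxel_p,
        n_permutations=n_permutations,
        seed=seed,
        mask=None if mask is None else np.asarray(mask, dtype=bool),
        maps=maps_v,
        flips=flips,
        valid=valid,
        dropped_voxels=dropped,
    )


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6, 18 or 26")


def cluster_correction(
    result: PermutationResult,
    height_alpha: float = 0.001,
    cluster_alpha: float = 0.05,
    connectivity: int = 26,
    height_stat: float | None = None,
) -> pd.DataFrame:
    """Cluster-extent FWE correction on a sign-flip test result.

    Voxels exceed the cluster-forming threshold when their statistic is
    strictly above the per-voxel permutation-null quantile at
    ``height_alpha`` (or a fixed statistic value ``height_stat`` if
    given).  The maximum suprathreshold cluster size per permutation
    forms the null; each observed cluster's FWE p is the proportion of
    null maxima at least as large.  An empty table (no suprathreshold
    voxels) is a valid outcome, not an error.
    """
    if result.mask is None:
        raise ValueError("cluster correction requires 3D mask geometry")
    structure = _connectivity_structure(connectivity)
    t_null = _one_sample_t(result.maps, result.flips)
    if height_stat is not None:
        thr = np.full(t_null.shape[1], float(height_stat))
    else:
        # value whose permutation voxel-p equals height_alpha: with the
        # identity in the null, suprathreshold (>=) matches p <= alpha
        thr = np.quantile(t_null, 1.0 - height_alpha, axis=0, method="higher")
    supra = t_null >= thr[None, :]

    mask_flat_idx = np.flatnonzero(result.mask.ravel())[result.valid]
    shape = result.mask.shape
    vol = np.zeros(shape, dtype=bool)

    n_perm = t_null.shape[0]
    null_max = np.zeros(n_perm, dtype=np.int64)
    for j in range(n_perm):
        vol.ravel()[:] = False
        vol.ravel()[mask_flat_idx] = supra[j]
        if vol.any():
            labels, n_lab = ndimage.label(vol, structure=structure)
            if n_lab:
                null_max[j] = np.bincount(labels.ravel())[1:].max()

    # observed clusters (identity row)
    vol.ravel()[:] = False
    vol.ravel()[mask_flat_idx] = supra[0]
    labels, n_lab = ndimage.label(vol, structure=structure)
    rows = []
    t_vol = np.full(shape, -np.inf)
    t_vol.ravel()[mask_flat_idx] = result.stat
    for lab in range(1, n_lab + 1):
        where = labels == lab
        size = int(where.sum())
        fwe_p = float((null_max >= size).mean())
        peak_flat = np.flatnonzero(where.ravel())[np.argmax(t_vol[where])]
        peak = tuple(int(i) for i in np.unravel_index(peak_flat, shape))
        rows.append(
            {
                "label": lab,
                "size": size,
                "peak_x": peak[0],
                "peak_y": peak[1],
                "peak_z": peak[2],
                "peak_stat": float(t_vol[peak]),
                "fwe_p": fwe_p,
                "significant": fwe_p < cluster_alpha,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "label",
            "size",
            "peak_x",
            "peak_y",
            "peak_z",
            "peak_stat",
            "fwe_p",
            "significant",
        ],
    )
    result.cluster_table = table
    result.null_max_cluster = null_max
    return table


def sign_flip_ttest_1samp(
    values: np.ndarray,
    n_permutations: int = 5000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Scalar one-sample sign-flip test (one-sided greater) on paired
    differences or ROI means.

    Full enumeration of all 2**n sign patterns replaces random sampling
    whenever 2**n <= n_permutations, making the p-value exact.
    Returns ``(t_statistic, p_value)``.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    if n <= 30 and 2**n <= n_permutations:
        # exact: enumerate all sign patterns; pattern 0 is the identity
        bits = np.arange(2**n, dtype=np.int64)
        flips = 1.0 - 2.0 * ((bits[:, None] >> np.arange(n)) & 1)
    else:
        rng = np.random.default_rng(seed)
        flips = _make_flips(n_permutations, n, rng)
    t_all = _one_sample_t(x[:, None], flips)[:, 0]
    t_obs = t_all[0]
    p = float((t_all >= t_obs).mean())
    return float(t_obs), p


def roi_summary(
    maps: np.ndarray,
    roi: np.ndarray,
    mask: np.ndarray | None = None,
    n_permutations: int = 5000,
    seed: int | None = None,
) -> dict:
    """Sign-flip test on per-subject mean contrast within an ROI.

    ``maps`` is (n_subjects, n_voxels) in mask order; ``roi`` is either a
    boolean vector over those voxels or a 3D boolean grid (with ``mask``
    giving the geometry).
    """
    maps = np.asarray(maps, dtype=float)
    roi = np.asarray(roi)
    if roi.ndim == 3:
        if mask is None:
            raise ValueError("3D ROI needs the analysis mask geometry")
        roi = roi.astype(bool)[np.asarray(mask, dtype=bool)]
    roi = roi.astype(bool)
    if roi.size != maps.shape[1]:
        raise ValueError("ROI length does not match voxel count")
    if not roi.any():
        raise ValueError("ROI lies entirely outside the analysis mask")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(maps[:, roi], axis=1)
    stat, p = sign_flip_ttest_1samp(means, n_permutations=n_permutations, seed=seed)
    return {"statistic": stat, "p": p, "subject_means": means}
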
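"""Voxelwise intersubject correlation: time-course extraction, leave-one-out
averaging, Pearson/Fisher machinery, subject contrast maps, and the
spatial-pattern (ISPS) variant.

Time courses are kept as ``(n_voxels, n_timepoints)`` float arrays in mask
order.  Voxels whose time course has zero variance yield an *undefined*
correlation, carried as NaN and excluded from group inference at that voxel
rather than being coerced to 0 (0 is a meaningful Fisher z).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .design import POOL_ALL, Cell, ConditionAssignment, CorrelationCellSet, ExperimentDesign

__all__ = [
    "fisher_z",
    "extract_video_timecourses",
    "loo_average",
    "voxelwise_correlation",
    "subject_contrast",
    "compute_contrast_maps",
    "spatial_pattern_similarity",
]

#: Clipping margin keeping arctanh finite at |r| = 1 while leaving
#: |r| <= 0.999999 untouched to six decimals.
FISHER_EPS = 1e-7


def fisher_z(r, eps: float = FISHER_EPS):
    """Variance-stabilizing Fisher transform, z = arctanh(r).

    Accepts scalars or arrays.  NaN (undefined correlation) propagates.
    Values outside [-1, 1] by more than a small numerical tolerance raise.
    """
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (np.abs(r) > 1.0 + 1e-9) & ~np.isnan(r)
    if np.any(bad):
        raise ValueError("correlation outside [-1, 1]")
    z = np.arctanh(np.clip(r, -1.0 + eps, 1.0 - eps))
    z = np.where(np.isnan(r), np.nan, z)
    return float(z) if z.ndim == 0 else z


def extract_video_timecourses(
    data: np.ndarray,
    mask: np.ndarray,
    design: ExperimentDesign,
) -> dict[str, np.ndarray]:
    """Slice one subject's 4D series into per-video masked time courses.

    The first ``design.trim_volumes`` volumes of each video are dropped to
    remove transient onset effects.  Returns, per video, an array of shape
    ``(n_mask_voxels, duration - trim)`` with voxels in ``mask`` order
    (C-order scan of the 3D grid).
    """
    data = np.asarray(data)
    mask = np.asarray(mask, dtype=bool)
    if data.ndim != 4:
        raise ValueError("expected a 4D array (x, y, z, t)")
    if mask.shape != data.shape[:3]:
        raise ValueError("mask geometry does not match data")
    if not mask.any():
        raise ValueError("mask is empty")
    n_t = data.shape[3]
    flat = data[mask]  # (n_vox, t)
    out: dict[str, np.ndarray] = {}
    for v in design.video_ids:
        onset = design.onsets_volumes[v]
        dur = design.durations_volumes[v]
        if onset + dur > n_t:
            raise ValueError(
                f"video {v!r} event [{onset}, {onset + dur}) exceeds series "
                f"length {n_t}"
            )
        out[v] = np.ascontiguousarray(
            flat[:, onset + design.trim_volumes : onset + dur], dtype=float
        )
    return out


def loo_average(
    pool: Mapping[str, np.ndarray], held_out: str
) -> np.ndarray:
    """Voxelwise mean time course over every pool member except ``held_out``."""
    if held_out not in pool:
        raise KeyError(f"held-out subject {held_out!r} not in pool")
    others = [np.asarray(ts, dtype=float) for s, ts in pool.items() if s != held_out]
    if not others:
        raise ValueError("leave-one-out pool is empty after exclusion")
    t = min(a.shape[-1] for a in others)
    return np.mean([a[..., :t] for a in others], axis=0)


def voxelwise_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r per voxel row between two time-course matrices.

    Series of unequal length are truncated to the shorter; fewer than 3
    overlapping timepoints is an error.  Zero-variance rows give NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("voxel counts differ")
    t = min(a.shape[1], b.shape[1])
    if t < 3:
        raise ValueError("need at least 3 overlapping timepoints")
    a = a[:, :t] - a[:, :t].mean(axis=1, keepdims=True)
    b = b[:, :t] - b[:, :t].mean(axis=1, keepdims=True)
    na = np.sqrt(np.einsum("ij,ij->i", a, a))
    nb = np.sqrt(np.einsum("ij,ij->i", b, b))
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->i", a, b) / denom
    r[denom == 0] = np.nan
    # guard accumulated rounding at |r| ~ 1
    return np.clip(r, -1.0, 1.0, out=r)


def subject_contrast(
    cells: Sequence[Cell], z_values: Mapping[Cell, np.ndarray]
) -> np.ndarray:
    """Weighted sum of Fisher-z maps over one subject's cells.

    With weights +1/#positive and -1/#negative this equals
    mean(z, positive cells) - mean(z, negative cells).  Undefined (NaN)
    voxels propagate.
    """
    missing = [c for c in cells if c not in z_values]
    if missing:
        raise ValueError(f"missing z-values for cells: {missing[:5]!r}")
    return sum(c.weight * np.asarray(z_values[c], dtype=float) for c in cells)


def _loo_mean_from_sums(total: np.ndarray, count: int, member: np.ndarray) -> np.ndarray:
    return (total - member) / (count - 1)


def compute_contrast_maps(
    timecourses: Mapping[str, Mapping[str, np.ndarray]],
    cellset: CorrelationCellSet,
) -> dict[str, np.ndarray]:
    """Per-subject Fisher-z contrast maps for a correlation-cell scheme.

    Parameters
    ----------
    timecourses:
        ``subject -> video -> (n_vox, t)`` masked time courses, as produced
        by :func:`extract_video_timecourses`.
    cellset:
        Output of :func:`~narsync.design.build_general_cells` or
        :func:`~narsync.design.build_condition_cells`.

    Returns
    -------
    dict mapping subject id to a ``(n_vox,)`` contrast map.

    Notes
    -----
    Leave-one-out averages are formed incrementally from per-pool sums, so
    the cost is linear in the number of cells.  Subjects missing a video
    are dropped from that video's cells and from others' LOO pools for it.
    """
    # group cells by (reference_video, pool) to share LOO sums
    pools: dict[tuple[str, str], list[str]] = {}
    for c in cellset.cells:
        key = (c.reference_video, c.pool)
        pools.setdefault(key, [])
    by_pool_members: dict[tuple[str, str], list[str]] = {}
    for (video, pool) in pools:
        if pool == POOL_ALL:
            members = [s for s in cellset.subjects if video in timecourses.get(s, {})]
        else:
            members = [
                s
                for s in cellset.subjects
                if _subject_pool(cellset, s) == pool and video in timecourses.get(s, {})
            ]
        by_pool_members[(video, pool)] = members

    sums: dict[tuple[str, str], np.ndarray] = {}
    tmins: dict[tuple[str, str], int] = {}
    for key, members in by_pool_members.items():
        video = key[0]
        series = [timecourses[s][video] for s in members]
        if not series:
            continue
        t = min(ts.shape[1] for ts in series)
        tmins[key] = t
        sums[key] = np.sum([ts[:, :t] for ts in series], axis=0, dtype=float)

    contrasts: dict[str, np.ndarray] = {}
    for s in cellset.subjects:
        pos: list[np.ndarray] = []
        neg: list[np.ndarray] = []
        for c in cellset.cells_for(s):
            if c.target_video not in timecourses.get(s, {}):
                continue  # subject missing this video: cell dropped
            key = (c.reference_video, c.pool)
            members = by_pool_members.get(key, [])
            own = timecourses[s][c.target_video]
            if s in members and c.reference_video == c.target_video:
                if len(members) < 2:
                    continue
                t = tmins[key]
                ref = _loo_mean_from_sums(sums[key], len(members), own[:, :t])
            else:
                # reference pool excludes the subject (different video, or
                # subject absent from the pool): plain LOO over members
                others = [m for m in members if m != s]
                if not others:
                    continue
                if s in members:
                    t = tmins[key]
                    ref = _loo_mean_from_sums(
                        sums[key], len(members), timecourses[s][c.reference_video][:, :t]
                    )
                else:
                    t = tmins[key]
                    ref = sums[key] / len(members)
            z = fisher_z(voxelwise_correlation(own, ref))
            (pos if c.weight > 0 else neg).append(z)
        if not pos or not neg:
            raise ValueError(f"subject {s!r} has no usable cells on one side")
        contrasts[s] = np.mean(pos, axis=0) - np.mean(neg, axis=0)
    return contrasts


def _subject_pool(cellset: CorrelationCellSet, subject: str) -> str:
    for c in cellset.cells:
        if c.subject_id == subject:
            return c.pool
    raise KeyError(subject)


def spatial_pattern_similarity(
    timecourses: Mapping[str, Mapping[str, np.ndarray]],
    cellset: CorrelationCellSet,
    roi_indices: np.ndarray,
) -> dict[str, float]:
    """Intersubject pattern similarity (ISPS) contrast, one scalar per subject.

    Each subject-video time course is averaged over time within the ROI,
    giving a spatial pattern; cells are evaluated as the Pearson
    correlation between the subject's pattern and the leave-one-out
    average pattern, Fisher transformed and contrasted exactly as the
    temporal scheme.
    """
    roi_indices = np.asarray(roi_indices)
    if roi_indices.size < 10:
        raise ValueError("ROI must contain at least 10 voxels")
    patterns = {
        s: {v: ts[roi_indices].mean(axis=1) for v, ts in vids.items()}
        for s, vids in timecourses.items()
    }
    out: dict[str, float] = {}
    for s in cellset.subjects:
        pos: list[float] = []
        neg: list[float] = []
        for c in cellset.cells_for(s):
            if c.pool == POOL_ALL:
                members = [m for m in cellset.subjects if c.reference_video in patterns.get(m, {})]
            else:
                members = [
                    m
                    for m in cellset.subjects
                    if _subject_pool(cellset, m) == c.pool
                    and c.reference_video in patterns.get(m, {})
                ]
            others = [patterns[m][c.reference_video] for m in members if m != s]
            if not others or c.target_video not in patterns.get(s, {}):
                continue
            ref = np.mean(others, axis=0)
            own = patterns[s][c.target_video]
            r = voxelwise_correlation(own[None, :], ref[None, :])[0]
            z = fisher_z(r)
            (pos if c.weight > 0 else neg).append(z)
        out[s] = float(np.mean(pos) - np.mean(neg))
    return out
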
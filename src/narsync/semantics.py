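"""Intersubject semantic consistency of recalled descriptions.

Each remembered recall is a d-dimensional sentence-embedding vector
(512 for the Universal Sentence Encoder family).  Within every
video x condition stratum, each subject's vector is correlated
(Pearson, across embedding dimensions) with the leave-one-subject-out
(LOSO) centroid — the mean vector of the *other* subjects who remembered
that video in the same condition.  Per-subject correlations are Fisher
transformed and averaged into one consistency score per video per
condition; the HC-vs-LC difference is tested with a video-level
sign-flip permutation on the paired differences (paired t statistic,
permutation null, exact enumeration when feasible).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import HC, LC
from .inference import sign_flip_ttest_1samp
from .isc import fisher_z

__all__ = [
    "filter_remembered",
    "loso_similarity",
    "video_condition_scores",
    "condition_difference_test",
    "ConsistencyTestResult",
    "embedding_columns",
]

META_COLUMNS = ("subject_id", "video_id", "condition", "remembered")


def embedding_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c not in META_COLUMNS]
    if len(cols) < 2:
        raise ValueError("embedding table needs at least 2 vector dimensions")
    return cols


def filter_remembered(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep only remembered trials; report per-stratum survivor counts.

    Returns the filtered table and a counts frame (``video_id``,
    ``condition``, ``n_remembered``, ``usable``); strata with fewer than
    2 remembered rows are flagged unusable (a LOSO centroid needs at
    least one other subject) and a warning is emitted.
    """
    if table.empty:
        raise ValueError("embedding table is empty")
    kept = table[table["remembered"].astype(bool)].copy()
    counts = (
        table.groupby(["video_id", "condition"], observed=True)["remembered"]
        .sum()
        .astype(int)
        .rename("n_remembered")
        .reset_index()
    )
    counts["usable"] = counts["n_remembered"] >= 2
    bad = counts[~counts["usable"]]
    if not bad.empty:
        strata = [f"{r.video_id}/{r.condition}" for r in bad.itertuples()]
        warnings.warn(
            f"strata with <2 remembered trials excluded: {', '.join(strata)}",
            stacklevel=2,
        )
    return kept, counts


def loso_similarity(stratum: pd.DataFrame) -> pd.DataFrame:
    """Per-subject similarity to the leave-one-subject-out centroid.

    ``stratum`` holds the remembered rows of one video x condition.
    Returns a frame with columns ``subject_id``, ``r``, ``z``; subjects
    whose LOSO centroid has zero variance get NaN (flagged undefined).
    """
    if len(stratum) < 2:
        raise ValueError("stratum needs at least 2 remembered rows")
    cols = embedding_columns(stratum)
    x = stratum[cols].to_numpy(dtype=float)
    n = x.shape[0]
    total = x.sum(axis=0)
    centroids = (total[None, :] - x) / (n - 1)
    xc = x - x.mean(axis=1, keepdims=True)
    cc = centroids - centroids.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", xc, cc)
    denom = np.sqrt(np.einsum("ij,ij->i", xc, xc) * np.einsum("ij,ij->i", cc, cc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
    r[denom == 0] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(
        {
            "subject_id": stratum["subject_id"].to_numpy(),
            "r": r,
            "z": fisher_z(r),
        }
    )


def video_condition_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Mean Fisher-z LOSO similarity per video x condition.

    Expects a remembered-only table (see :func:`filter_remembered`).
    Strata with fewer than 2 rows are excluded with a reason code in the
    returned frame's companion rows (``excluded`` / ``reason`` columns).
    """
    rows = []
    for (video, cond), stratum in table.groupby(
        ["video_id", "condition"], observed=True
    ):
        if len(stratum) < 2:
            rows.append(
                {
                    "video_id": video,
                    "condition": cond,
                    "n": len(stratum),
                    "mean_z": np.nan,
                    "excluded": True,
                    "reason": "fewer than 2 remembered trials",
                }
            )
            continue
        sims = loso_similarity(stratum)
        rows.append(
            {
                "video_id": video,
                "condition": cond,
                "n": int(sims["z"].notna().sum()),
                "mean_z": float(sims["z"].mean(skipna=True)),
                "excluded": False,
                "reason": "",
            }
        )
    return pd.DataFrame(rows).sort_values(["video_id", "condition"]).reset_index(
        drop=True
    )


@dataclass(frozen=True)
class ConsistencyTestResult:
    statistic: float          # paired t across videos
    p: float                  # one-sided (HC > LC), permutation null
    n_videos: int
    n_permutations: int
    seed: int | None
    differences: pd.Series    # per-video HC - LC mean z
    dropped_videos: tuple[str, ...]


def condition_difference_test(
    scores: pd.DataFrame,
    n_permutations: int = 5000,
    seed: int | None = None,
) -> ConsistencyTestResult:
    """Video-level sign-flip permutation test of HC > LC consistency.

    ``scores`` is the output of :func:`video_condition_scores`.  Videos
    missing either condition (or excluded) are dropped with a warning.
    The observed statistic is the paired t over per-video differences;
    its null is built by flipping each video's difference sign, with
    exhaustive enumeration whenever 2**V <= n_permutations.
    """
    usable = scores[~scores["excluded"]] if "excluded" in scores else scores
    wide = usable.pivot(index="video_id", columns="condition", values="mean_z")
    have_both = wide.notna().all(axis=1) if {HC, LC} <= set(wide.columns) else (
        pd.Series(False, index=wide.index)
    )
    dropped = tuple(wide.index[~have_both])
    if dropped:
        warnings.warn(
            f"videos missing one condition dropped: {', '.join(dropped)}",
            stacklevel=2,
        )
    wide = wide[have_both]
    if len(wide) < 5:
        raise ValueError("need at least 5 videos with both conditions")
    diffs = wide[HC] - wide[LC]
    stat, p = sign_flip_ttest_1samp(
        diffs.to_numpy(), n_permutations=n_permutations, seed=seed
    )
    return ConsistencyTestResult(
        statistic=stat,
        p=p,
        n_videos=len(diffs),
        n_permutations=n_permutations,
        seed=seed,
        differences=diffs,
        dropped_videos=dropped,
    )
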
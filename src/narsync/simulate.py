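"""Synthetic cohorts with the statistical structure the analyses assume.

The BOLD simulator produces, for every video, a smooth latent time course
shared by all viewers (temporally smoothed white noise — intersubject
correlation is invariant to the latent's spectrum, so no hemodynamic
model is imposed).  Each subject's voxel signal is that latent scaled by
a gain, plus idiosyncratic Gaussian noise; inside a designated effect
region the gain receives an extra boost when the subject watched the
video in the high-context (HC) condition.  The recall-embedding
simulator draws, per video, a centroid vector in a d-dimensional
semantic space and scatters each subject's recall vector around it with
condition-specific isotropic dispersion; tighter HC dispersion is the
planted analogue of more consistent recall.

Both simulators are deterministic given their seed and return the
planted ground truth alongside the data, enabling parameter-recovery and
calibration tests downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .design import HC, LC, ConditionAssignment, ExperimentDesign

__all__ = [
    "BoldSimConfig",
    "EmbeddingSimConfig",
    "BoldCohort",
    "make_design",
    "make_assignment",
    "simulate_bold_cohort",
    "simulate_recall_embeddings",
]


def make_design(
    n_videos: int = 20,
    n_runs: int = 4,
    tr_seconds: float = 2.62,
    trim_volumes: int = 2,
    duration_volumes: int = 13,
    gap_volumes: int = 6,
) -> ExperimentDesign:
    """A regular design: V videos over R equal runs, back-to-back events.

    Defaults mirror a study of twenty ~34 s sitcom clips at TR 2.62 s
    (13 volumes per clip) in four runs of five, with a short filled gap
    between clips.
    """
    if n_videos % n_runs:
        raise ValueError("n_videos must divide evenly into n_runs")
    ids = tuple(f"v{i + 1:02d}" for i in range(n_videos))
    m = n_videos // n_runs
    runs = tuple(ids[i * m : (i + 1) * m] for i in range(n_runs))
    onsets = {
        v: gap_volumes + i * (duration_volumes + gap_volumes)
        for i, v in enumerate(ids)
    }
    durations = {v: duration_volumes for v in ids}
    return ExperimentDesign(ids, runs, tr_seconds, trim_volumes, onsets, durations)


def make_assignment(
    design: ExperimentDesign,
    n_subjects: int,
    seed: int | None = None,
    subject_ids: tuple[str, ...] | None = None,
) -> ConditionAssignment:
    """Two complementary condition lists split (near-)evenly over subjects.

    Within every run, half the videos (rounding alternating per run when
    the run size is odd) are HC in list A and LC in list B, chosen at
    random per seed.  A 19-subject cohort therefore lands 9 subjects in
    one list and 10 in the other.
    """
    rng = np.random.default_rng(seed)
    if subject_ids is None:
        subject_ids = tuple(f"sub-{i + 1:02d}" for i in range(n_subjects))
    list_a: dict[str, str] = {}
    need_hc = design.n_videos // 2
    if 2 * need_hc != design.n_videos:
        raise ValueError("counterbalancing needs an even number of videos")
    # draw HC picks run by run, balancing the global count
    picked: list[str] = []
    carry = 0.0
    for run in design.runs:
        k_f = len(run) / 2 + carry
        k = int(round(k_f))
        carry = k_f - k
        chosen = rng.choice(len(run), size=k, replace=False)
        picked.extend(run[i] for i in chosen)
    # fix up rounding so the global split is exact
    while len(picked) > need_hc:
        picked.pop()
    if len(picked) < need_hc:
        rest = [v for v in design.video_ids if v not in picked]
        picked.extend(rest[: need_hc - len(picked)])
    hc_set = set(picked)
    for v in design.video_ids:
        list_a[v] = HC if v in hc_set else LC
    list_b = {v: (LC if c == HC else HC) for v, c in list_a.items()}
    half = n_subjects // 2
    conditions = {}
    list_ids = {}
    for i, s in enumerate(subject_ids):
        if i < half:
            conditions[s], list_ids[s] = dict(list_a), "A"
        else:
            conditions[s], list_ids[s] = dict(list_b), "B"
    return ConditionAssignment(subject_ids, conditions, list_ids)


@dataclass(frozen=True)
class BoldSimConfig:
    """Parameters of the shared-signal BOLD simulator.

    ``shared_gain_base`` scales the latent shared by all viewers of a
    video; ``shared_gain_hc_boost`` is added to the gain inside
    ``effect_region`` when the video is watched in the HC condition.
    ``noise_sd`` is the standard deviation of the idiosyncratic noise
    (latents are unit-variance, so base/noise_sd is the shared-signal
    amplitude ratio).
    """

    n_subjects: int
    grid_shape: tuple[int, int, int]
    design: ExperimentDesign
    assignment: ConditionAssignment
    effect_region: np.ndarray = field(default=None)  # 3D bool
    shared_gain_base: float = 1.0
    shared_gain_hc_boost: float = 0.0
    noise_sd: float = 1.0
    smooth_width: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.shared_gain_base < 0 or self.shared_gain_hc_boost < 0:
            raise ValueError("gains must be non-negative")
        region = self.effect_region
        if region is None:
            region = np.zeros(self.grid_shape, dtype=bool)
        region = np.asarray(region, dtype=bool)
        if region.shape != tuple(self.grid_shape):
            raise ValueError(
                f"effect_region shape {region.shape} does not fit grid "
                f"{tuple(self.grid_shape)}"
            )
        object.__setattr__(self, "effect_region", region)
        if len(self.assignment.subject_ids) != self.n_subjects:
            raise ValueError("assignment does not cover n_subjects")


@dataclass
class BoldCohort:
    """Simulated 4D data per subject plus planted ground truth."""

    data: dict[str, np.ndarray]          # subject -> (x, y, z, t)
    latents: dict[str, np.ndarray]       # video -> shared latent time course
    effect_region: np.ndarray
    config: BoldSimConfig


def _smooth_latent(rng: np.random.Generator, n: int, width: int) -> np.ndarray:
    """Unit-variance moving-average latent of length n."""
    w = max(int(width), 1)
    raw = rng.standard_normal(n + w - 1)
    kernel = np.ones(w) / w
    g = np.convolve(raw, kernel, mode="valid")
    g = g - g.mean()
    sd = g.std()
    return g / sd if sd > 0 else g


def simulate_bold_cohort(config: BoldSimConfig) -> BoldCohort:
    """Generate one cohort of stimulus-locked 4D series.

    For video v, voxel x, subject s, during the video's event window::

        signal(t) = g_v(t) * (base + boost * [x in region and cond(s,v)=HC])
                    + noise

    with g_v a per-video smooth unit-variance latent shared by all
    subjects.  Volumes outside every event are pure noise.
    """
    design = config.design
    rng = np.random.default_rng(config.seed)
    n_t = design.n_volumes
    latents = {
        v: _smooth_latent(rng, design.durations_volumes[v], config.smooth_width)
        for v in design.video_ids
    }
    region_flat = config.effect_region.ravel()
    n_vox = int(np.prod(config.grid_shape))
    data: dict[str, np.ndarray] = {}
    for s in config.assignment.subject_ids:
        vol = rng.standard_normal((n_vox, n_t)) * config.noise_sd
        for v in design.video_ids:
            onset = design.onsets_volumes[v]
            dur = design.durations_volumes[v]
            gain = np.full(n_vox, config.shared_gain_base)
            if config.assignment.condition(s, v) == HC:
                gain[region_flat] += config.shared_gain_hc_boost
            vol[:, onset : onset + dur] += gain[:, None] * latents[v][None, :]
        data[s] = vol.reshape(*config.grid_shape, n_t)
    return BoldCohort(data, latents, config.effect_region, config)


@dataclass(frozen=True)
class EmbeddingSimConfig:
    """Parameters of the recall-embedding simulator.

    ``sigma_hc < sigma_lc`` plants the effect that recall of videos seen
    with prior knowledge is more consistent across subjects.
    """

    n_subjects: int
    n_videos: int = 20
    dim: int = 512
    centroid_scale: float = 1.0
    sigma_hc: float = 0.5
    sigma_lc: float = 1.0
    p_remembered_hc: float = 0.84
    p_remembered_lc: float = 0.69
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_hc <= 0 or self.sigma_lc <= 0:
            raise ValueError("dispersions must be positive")
        if self.dim < 2:
            raise ValueError("dim must be at least 2")
        for p in (self.p_remembered_hc, self.p_remembered_lc):
            if not 0.0 <= p <= 1.0:
                raise ValueError("remember probabilities must lie in [0, 1]")
        if self.n_videos % 2:
            raise ValueError("n_videos must be even for counterbalancing")


def simulate_recall_embeddings(
    config: EmbeddingSimConfig,
) -> tuple[pd.DataFrame, dict]:
    """Recall-embedding table with condition-dependent intersubject spread.

    Subjects split into two complementary condition lists.  Each
    remembered flag is Bernoulli with the condition's probability.
    Returns the long-format table (columns ``subject_id``, ``video_id``,
    ``condition``, ``remembered``, ``v0`` ... ``v{dim-1}``) and a
    ground-truth dict with the per-video centroids.
    """
    rng = np.random.default_rng(config.seed)
    videos = [f"v{i + 1:02d}" for i in range(config.n_videos)]
    subjects = [f"sub-{i + 1:03d}" for i in range(config.n_subjects)]
    centroids = {
        v: rng.standard_normal(config.dim) * config.centroid_scale for v in videos
    }
    half_v = config.n_videos // 2
    list_a = {v: (HC if i < half_v else LC) for i, v in enumerate(videos)}
    list_b = {v: (LC if c == HC else HC) for v, c in list_a.items()}
    sigma = {HC: config.sigma_hc, LC: config.sigma_lc}
    p_rem = {HC: config.p_remembered_hc, LC: config.p_remembered_lc}
    rows = []
    vecs = []
    for i, s in enumerate(subjects):
        mapping = list_a if i < config.n_subjects // 2 else list_b
        for v in videos:
            cond = mapping[v]
            vec = centroids[v] + rng.standard_normal(config.dim) * sigma[cond]
            remembered = bool(rng.random() < p_rem[cond])
            rows.append(
                {
                    "subject_id": s,
                    "video_id": v,
                    "condition": cond,
                    "remembered": remembered,
                }
            )
            vecs.append(vec)
    table = pd.DataFrame(rows)
    vec_df = pd.DataFrame(
        np.asarray(vecs), columns=[f"v{i}" for i in range(config.dim)]
    )
    table = pd.concat([table, vec_df], axis=1)
    truth = {"centroids": centroids, "sigma": sigma, "config": config}
    return table, truth
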
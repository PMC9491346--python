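"""Experimental design and correlation-cell construction.

An experiment presents V short videos split over R runs of equal size m.
Each subject sees every video once; half the videos are seen in the
high-context (HC) condition and half in the low-context (LC) condition,
counterbalanced over exactly two complementary condition lists.

Two intersubject-correlation (ISC) schemes are defined as sets of
"correlation cells" with signed contrast weights:

* ``general`` — per subject, one cell correlating the subject's time
  course for each video with the leave-one-out (LOO) average of all other
  subjects watching the *same* video, plus one cell per ordered pair
  (video, other video in the same run) against the LOO average for the
  *other* video.  The contrast is same-video minus different-video.
* ``prior_knowledge`` — per subject, one same-video cell per video, with
  the LOO pool restricted to subjects in the same condition list; cells
  are labelled HC or LC by the subject's condition for that video, and the
  contrast is HC minus LC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

__all__ = [
    "ExperimentDesign",
    "ConditionAssignment",
    "Cell",
    "CorrelationCellSet",
    "build_general_cells",
    "build_condition_cells",
]

HC = "HC"
LC = "LC"

#: LOO pool spanning every subject (general scheme).
POOL_ALL = "__all__"


@dataclass(frozen=True)
class ExperimentDesign:
    """Videos, run structure and event timing, in volume units.

    Parameters
    ----------
    video_ids:
        Ordered video identifiers (length V).
    runs:
        Partition of ``video_ids`` into R ordered runs of equal size m.
    tr_seconds:
        Repetition time of the functional acquisition, in seconds.
    trim_volumes:
        Number of initial volumes discarded from each video's time course
        to remove transient onset effects.
    onsets_volumes, durations_volumes:
        Per-video onset and duration, as 0-based volume indices / counts
        into each subject's concatenated functional series.
    """

    video_ids: tuple[str, ...]
    runs: tuple[tuple[str, ...], ...]
    tr_seconds: float
    trim_volumes: int
    onsets_volumes: Mapping[str, int]
    durations_volumes: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "video_ids", tuple(self.video_ids))
        object.__setattr__(self, "runs", tuple(tuple(r) for r in self.runs))
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.trim_volumes < 0:
            raise ValueError("trim_volumes must be non-negative")
        flat = [v for run in self.runs for v in run]
        if sorted(flat) != sorted(self.video_ids) or len(set(flat)) != len(flat):
            raise ValueError("runs must partition video_ids exactly")
        sizes = {len(r) for r in self.runs}
        if len(sizes) != 1:
            raise ValueError("all runs must have equal size")
        for v in self.video_ids:
            if v not in self.onsets_volumes or v not in self.durations_volumes:
                raise ValueError(f"missing event timing for video {v!r}")
            if self.onsets_volumes[v] < 0 or self.durations_volumes[v] < 0:
                raise ValueError(f"negative onset/duration for video {v!r}")
            if self.durations_volumes[v] - self.trim_volumes < 3:
                raise ValueError(
                    f"video {v!r}: duration {self.durations_volumes[v]} leaves "
                    f"fewer than 3 usable timepoints after trimming "
                    f"{self.trim_volumes}"
                )

    @property
    def n_videos(self) -> int:
        return len(self.video_ids)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def run_size(self) -> int:
        return len(self.runs[0])

    @property
    def trim_seconds(self) -> float:
        """Seconds of signal removed from each video's onset."""
        return self.trim_volumes * self.tr_seconds

    def run_of(self, video_id: str) -> tuple[str, ...]:
        for run in self.runs:
            if video_id in run:
                return run
        raise KeyError(video_id)

    def usable_timepoints(self, video_id: str) -> int:
        return self.durations_volumes[video_id] - self.trim_volumes

    @property
    def n_volumes(self) -> int:
        """Minimum series length covering every event."""
        return max(
            self.onsets_volumes[v] + self.durations_volumes[v]
            for v in self.video_ids
        )


@dataclass(frozen=True)
class ConditionAssignment:
    """Per-subject HC/LC labels, organized in two complementary lists."""

    subject_ids: tuple[str, ...]
    conditions: Mapping[str, Mapping[str, str]]
    list_ids: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        by_list: dict[str, dict[str, str]] = {}
        for s in self.subject_ids:
            if s not in self.conditions or s not in self.list_ids:
                raise ValueError(f"subject {s!r} missing condition mapping or list id")
            cond = dict(self.conditions[s])
            vals = set(cond.values())
            if not vals <= {HC, LC}:
                raise ValueError(f"subject {s!r}: conditions must be HC or LC")
            n_hc = sum(1 for c in cond.values() if c == HC)
            if 2 * n_hc != len(cond):
                raise ValueError(
                    f"subject {s!r}: expected half HC, got {n_hc}/{len(cond)}"
                )
            lid = self.list_ids[s]
            if lid in by_list:
                if by_list[lid] != cond:
                    raise ValueError(
                        f"subjects in condition list {lid!r} disagree on mapping"
                    )
            else:
                by_list[lid] = cond
        lists = list(by_list.values())
        if len(lists) > 2:
            raise ValueError("at most two complementary condition lists supported")
        if len(lists) == 2:
            a, b = lists
            if set(a) != set(b) or any(a[v] == b[v] for v in a):
                raise ValueError("condition lists must be complementary")

    def condition(self, subject_id: str, video_id: str) -> str:
        return self.conditions[subject_id][video_id]

    @property
    def list_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(self.list_ids[s], None)
        return tuple(seen)

    def list_members(self, list_id: str) -> tuple[str, ...]:
        return tuple(s for s in self.subject_ids if self.list_ids[s] == list_id)

    def flipped(self) -> "ConditionAssignment":
        """Swap every subject's HC/LC labels (lists trade mappings)."""
        flip = {HC: LC, LC: HC}
        return ConditionAssignment(
            subject_ids=self.subject_ids,
            conditions={
                s: {v: flip[c] for v, c in self.conditions[s].items()}
                for s in self.subject_ids
            },
            list_ids=dict(self.list_ids),
        )


class Cell(NamedTuple):
    """One correlation of interest.

    ``reference_video`` is the video whose LOO average time course the
    subject's ``target_video`` time course is correlated with; ``pool`` is
    either :data:`POOL_ALL` or a condition-list id restricting the LOO
    pool; ``kind`` labels the cell's role in the contrast.
    """

    subject_id: str
    target_video: str
    reference_video: str
    pool: str
    kind: str
    weight: float


@dataclass(frozen=True)
class CorrelationCellSet:
    scheme: str
    subjects: tuple[str, ...]
    cells: tuple[Cell, ...] = field(repr=False)

    def cells_for(self, subject_id: str) -> tuple[Cell, ...]:
        return tuple(c for c in self.cells if c.subject_id == subject_id)

    def weight_sum(self, subject_id: str) -> float:
        return sum(c.weight for c in self.cells_for(subject_id))


def build_general_cells(
    design: ExperimentDesign, subjects: Sequence[str]
) -> CorrelationCellSet:
    """Same-video vs different-video (within run) contrast cells.

    For the full design of 20 videos in 4 runs of 5 this yields 100 cells
    per subject: 20 same-video and 80 different-video.
    """
    subjects = tuple(subjects)
    if len(subjects) < 3:
        raise ValueError(
            "general ISC needs at least 3 subjects for leave-one-out pools"
        )
    if design.run_size < 2:
        raise ValueError("runs of size 1 admit no different-video cells")
    n_same = design.n_videos
    n_diff = design.n_videos * (design.run_size - 1)
    w_same = 1.0 / n_same
    w_diff = -1.0 / n_diff
    cells = []
    for s in subjects:
        for run in design.runs:
            for v in run:
                cells.append(Cell(s, v, v, POOL_ALL, "same", w_same))
                for other in run:
                    if other != v:
                        cells.append(Cell(s, v, other, POOL_ALL, "different", w_diff))
    return CorrelationCellSet("general", subjects, tuple(cells))


def build_condition_cells(
    design: ExperimentDesign, assignment: ConditionAssignment
) -> CorrelationCellSet:
    """HC vs LC same-video cells with list-restricted LOO pools.

    For 20 videos this yields 20 cells per subject: 10 HC and 10 LC.
    """
    for lid in assignment.list_names:
        if len(assignment.list_members(lid)) < 3:
            raise ValueError(
                f"condition list {lid!r} has fewer than 3 subjects; "
                "leave-one-out pool is degenerate"
            )
    half = design.n_videos // 2
    if 2 * half != design.n_videos:
        raise ValueError("prior-knowledge contrast needs an even video count")
    cells = []
    for s in assignment.subject_ids:
        lid = assignment.list_ids[s]
        for v in design.video_ids:
            cond = assignment.condition(s, v)
            w = 1.0 / half if cond == HC else -1.0 / half
            cells.append(Cell(s, v, v, lid, cond.lower(), w))
    return CorrelationCellSet("prior_knowledge", assignment.subject_ids, tuple(cells))
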
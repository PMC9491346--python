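"""File formats: design YAML, NIfTI volumes, embedding CSV, provenance JSON.

The design file is a single YAML document::

    tr_seconds: 2.62
    trim_volumes: 2
    runs: [[v01, v02], [v03, v04]]
    events: {v01: {onset: 0, duration: 13}, ...}
    condition_lists: {A: {v01: HC, v02: LC, ...}, B: {...}}
    subjects: {sub-01: A, sub-02: B, ...}

NIfTI I/O goes through nibabel; unless an affine is supplied, volumes are
written with an isotropic diagonal affine at the stated voxel size.
Every artifact writer can attach a JSON provenance sidecar recording the
inputs, parameters and seed that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .design import ConditionAssignment, ExperimentDesign

__all__ = [
    "load_design",
    "save_design",
    "load_nifti",
    "save_nifti",
    "load_embeddings",
    "save_embeddings",
    "write_provenance",
]


def save_design(
    path: str | Path,
    design: ExperimentDesign,
    assignment: ConditionAssignment | None = None,
) -> None:
    doc: dict[str, Any] = {
        "tr_seconds": float(design.tr_seconds),
        "trim_volumes": int(design.trim_volumes),
        "runs": [list(run) for run in design.runs],
        "events": {
            v: {
                "onset": int(design.onsets_volumes[v]),
                "duration": int(design.durations_volumes[v]),
            }
            for v in design.video_ids
        },
    }
    if assignment is not None:
        lists: dict[str, Mapping[str, str]] = {}
        for s in assignment.subject_ids:
            lists.setdefault(assignment.list_ids[s], assignment.conditions[s])
        doc["condition_lists"] = {k: dict(v) for k, v in lists.items()}
        doc["subjects"] = {
            s: assignment.list_ids[s] for s in assignment.subject_ids
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_design(
    path: str | Path,
) -> tuple[ExperimentDesign, ConditionAssignment | None]:
    doc = yaml.safe_load(Path(path).read_text())
    runs = tuple(tuple(r) for r in doc["runs"])
    video_ids = tuple(v for run in runs for v in run)
    design = ExperimentDesign(
        video_ids=video_ids,
        runs=runs,
        tr_seconds=float(doc["tr_seconds"]),
        trim_volumes=int(doc["trim_volumes"]),
        onsets_volumes={v: int(doc["events"][v]["onset"]) for v in video_ids},
        durations_volumes={v: int(doc["events"][v]["duration"]) for v in video_ids},
    )
    assignment = None
    if "subjects" in doc and "condition_lists" in doc:
        subjects = tuple(doc["subjects"])
        assignment = ConditionAssignment(
            subject_ids=subjects,
            conditions={
                s: dict(doc["condition_lists"][doc["subjects"][s]])
                for s in subjects
            },
            list_ids={s: doc["subjects"][s] for s in subjects},
        )
    return design, assignment


def save_nifti(
    path: str | Path,
    data: np.ndarray,
    affine: np.ndarray | None = None,
    voxel_size_mm: float = 3.0,
) -> None:
    if affine is None:
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine) from a .nii/.nii.gz file."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_embeddings(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def load_embeddings(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"subject_id", "video_id", "condition", "remembered"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"embedding table missing columns: {sorted(missing)}")
    table["remembered"] = table["remembered"].astype(bool)
    return table


def write_provenance(path: str | Path, record: Mapping[str, Any]) -> None:
    """JSON sidecar with enough detail to re-run the producing stage."""
    from . import __version__

    doc = {"narsync_version": __version__, **record}
    Path(path).write_text(json.dumps(doc, indent=2, default=str) + "\n")
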
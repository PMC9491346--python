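"""End-to-end pipeline: simulate -> mask -> extract -> cells -> contrasts
-> group inference -> semantic consistency.

Driven by a YAML config; every stage writes its artifacts plus a JSON
provenance sidecar, and the run as a whole writes ``manifest.json``.
A minimal config requesting simulation::

    seed: 7
    simulate:
      n_subjects: 8
      grid: [8, 8, 8]
      n_videos: 4
      n_runs: 2
      duration_volumes: 20
      shared_gain_base: 1.0
      shared_gain_hc_boost: 0.0
      noise_sd: 1.0
    embeddings:
      n_subjects: 40
      n_videos: 8
      dim: 64
    group:
      n_permutations: 1000
      height_alpha: 0.01
      cluster_alpha: 0.05
      connectivity: 26
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io
from .design import build_condition_cells, build_general_cells
from .inference import cluster_correction, sign_flip_test
from .isc import compute_contrast_maps, extract_video_timecourses
from .mask import build_graymatter_mask
from .semantics import (
    condition_difference_test,
    filter_remembered,
    video_condition_scores,
)
from .simulate import (
    BoldSimConfig,
    EmbeddingSimConfig,
    make_assignment,
    make_design,
    simulate_bold_cohort,
    simulate_recall_embeddings,
)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


@_stage("simulate")
def _simulate_stage(cfg: Mapping[str, Any], seed: int, outdir: Path):
    sim = cfg["simulate"]
    design = make_design(
        n_videos=int(sim.get("n_videos", 4)),
        n_runs=int(sim.get("n_runs", 2)),
        tr_seconds=float(sim.get("tr_seconds", 2.62)),
        trim_volumes=int(sim.get("trim_volumes", 2)),
        duration_volumes=int(sim.get("duration_volumes", 20)),
        gap_volumes=int(sim.get("gap_volumes", 4)),
    )
    n_subjects = int(sim.get("n_subjects", 8))
    assignment = make_assignment(design, n_subjects, seed=seed)
    grid = tuple(int(g) for g in sim.get("grid", (8, 8, 8)))
    region = np.zeros(grid, dtype=bool)
    slabs = sim.get("effect_region")
    if slabs:  # [[x0, x1], [y0, y1], [z0, z1]] half-open slabs
        (x0, x1), (y0, y1), (z0, z1) = slabs
        region[x0:x1, y0:y1, z0:z1] = True
    config = BoldSimConfig(
        n_subjects=n_subjects,
        grid_shape=grid,
        design=design,
        assignment=assignment,
        effect_region=region,
        shared_gain_base=float(sim.get("shared_gain_base", 1.0)),
        shared_gain_hc_boost=float(sim.get("shared_gain_hc_boost", 0.0)),
        noise_sd=float(sim.get("noise_sd", 1.0)),
        smooth_width=int(sim.get("smooth_width", 5)),
        seed=seed,
    )
    cohort = simulate_bold_cohort(config)
    vox = float(sim.get("voxel_size_mm", 3.0))
    for s, vol in cohort.data.items():
        io.save_nifti(outdir / f"{s}_bold.nii.gz", vol.astype(np.float32), voxel_size_mm=vox)
    io.save_nifti(outdir / "effect_region.nii.gz", region.astype(np.uint8), voxel_size_mm=vox)
    io.save_design(outdir / "design.yaml", design, assignment)
    io.write_provenance(
        outdir / "simulate.json",
        {"stage": "simulate", "seed": seed, "parameters": dict(sim)},
    )
    return design, assignment, cohort


@_stage("mask")
def _mask_stage(cfg: Mapping[str, Any], grid: tuple[int, ...], outdir: Path):
    mcfg = cfg.get("mask", {})
    # synthetic cohorts carry signal everywhere: a uniform probability map
    prob = np.full(grid, float(mcfg.get("probability", 0.5)))
    gm = build_graymatter_mask(
        [prob],
        fwhm_mm=float(mcfg.get("fwhm_mm", 0.0)),
        threshold=float(mcfg.get("threshold", 0.3)),
        voxel_size_mm=float(mcfg.get("voxel_size_mm", 3.0)),
    )
    io.save_nifti(outdir / "graymatter_mask.nii.gz", gm.mask.astype(np.uint8))
    io.write_provenance(
        outdir / "mask.json",
        {"stage": "mask", "threshold": gm.threshold, "fwhm_mm": gm.fwhm_mm},
    )
    return gm


@_stage("isc")
def _isc_stage(design, assignment, cohort, gm, outdir: Path):
    timecourses = {
        s: extract_video_timecourses(vol, gm.mask, design)
        for s, vol in cohort.data.items()
    }
    general = build_general_cells(design, assignment.subject_ids)
    condition = build_condition_cells(design, assignment)
    maps = {
        "general": compute_contrast_maps(timecourses, general),
        "prior_knowledge": compute_contrast_maps(timecourses, condition),
    }
    for scheme, per_subject in maps.items():
        for s, m in per_subject.items():
            vol = np.full(gm.mask.shape, np.nan, dtype=np.float32)
            vol[gm.mask] = m
            io.save_nifti(outdir / f"{s}_{scheme}_contrast.nii.gz", vol)
    io.write_provenance(
        outdir / "isc.json",
        {
            "stage": "isc",
            "schemes": list(maps),
            "n_subjects": len(assignment.subject_ids),
        },
    )
    return maps


@_stage("group")
def _group_stage(cfg: Mapping[str, Any], maps, gm, seed: int, outdir: Path):
    gcfg = cfg.get("group", {})
    n_perm = int(gcfg.get("n_permutations", 1000))
    results = {}
    for scheme, per_subject in maps.items():
        stacked = np.asarray([per_subject[s] for s in sorted(per_subject)])
        res = sign_flip_test(stacked, n_permutations=n_perm, seed=seed, mask=gm.mask)
        table = cluster_correction(
            res,
            height_alpha=float(gcfg.get("height_alpha", 0.001)),
            cluster_alpha=float(gcfg.get("cluster_alpha", 0.05)),
            connectivity=int(gcfg.get("connectivity", 26)),
        )
        io.save_nifti(outdir / f"group_{scheme}_t.nii.gz", res.stat_volume())
        pvol = np.full(gm.mask.shape, np.nan)
        idx = np.flatnonzero(gm.mask.ravel())[res.valid]
        pvol.ravel()[idx] = res.voxel_p
        io.save_nifti(outdir / f"group_{scheme}_voxel_p.nii.gz", pvol)
        table.to_csv(outdir / f"group_{scheme}_clusters.csv", index=False)
        io.write_provenance(
            outdir / f"group_{scheme}.json",
            {
                "stage": "group",
                "scheme": scheme,
                "n_permutations": n_perm,
                "seed": seed,
                "height_alpha": float(gcfg.get("height_alpha", 0.001)),
                "cluster_alpha": float(gcfg.get("cluster_alpha", 0.05)),
                "connectivity": int(gcfg.get("connectivity", 26)),
                "dropped_voxels": res.dropped_voxels,
            },
        )
        results[scheme] = res
    return results


@_stage("semantics")
def _semantics_stage(cfg: Mapping[str, Any], seed: int, outdir: Path):
    ecfg = cfg.get("embeddings", {})
    config = EmbeddingSimConfig(
        n_subjects=int(ecfg.get("n_subjects", 40)),
        n_videos=int(ecfg.get("n_videos", 8)),
        dim=int(ecfg.get("dim", 64)),
        centroid_scale=float(ecfg.get("centroid_scale", 1.0)),
        sigma_hc=float(ecfg.get("sigma_hc", 0.5)),
        sigma_lc=float(ecfg.get("sigma_lc", 1.0)),
        p_remembered_hc=float(ecfg.get("p_remembered_hc", 0.84)),
        p_remembered_lc=float(ecfg.get("p_remembered_lc", 0.69)),
        seed=seed,
    )
    table, _ = simulate_recall_embeddings(config)
    io.save_embeddings(outdir / "embeddings.csv", table)
    kept, counts = filter_remembered(table)
    scores = video_condition_scores(kept)
    scores.to_csv(outdir / "consistency_scores.csv", index=False)
    n_perm = int(ecfg.get("n_permutations", 5000))
    result = condition_difference_test(scores, n_permutations=n_perm, seed=seed)
    io.write_provenance(
        outdir / "semantics.json",
        {
            "stage": "semantics",
            "statistic": result.statistic,
            "p": result.p,
            "n_videos": result.n_videos,
            "n_permutations": result.n_permutations,
            "seed": seed,
        },
    )
    return result


def run_pipeline(config: str | Path | Mapping[str, Any], outdir: str | Path) -> Path:
    """Run every stage of the analysis on a simulated cohort.

    ``config`` is a YAML path or an equivalent mapping; ``outdir``
    receives all artifacts and a ``manifest.json`` listing them.
    """
    if isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text())
    else:
        cfg = dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    design, assignment, cohort = _simulate_stage(cfg, seed, outdir)
    gm = _mask_stage(cfg, cohort.data[assignment.subject_ids[0]].shape[:3], outdir)
    maps = _isc_stage(design, assignment, cohort, gm, outdir)
    _group_stage(cfg, maps, gm, seed, outdir)
    sem = _semantics_stage(cfg, seed, outdir)

    manifest = {
        "seed": seed,
        "config": cfg,
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
        "semantic_test": {"statistic": sem.statistic, "p": sem.p},
    }
    from . import __version__

    manifest["narsync_version"] = __version__
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir
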
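"""End-to-end orchestration: simulate -> segment -> mesh -> deform ->
measure -> correlate.

Each synthetic subject gets a phantom whose target whole-breast density
is that subject's cohort draw; the phantom is segmented, meshed,
deformed from prone to a depth-matched supine configuration, and the
elastography ROI density is measured on the warped labels at the
subject's ROI depth. The cohort statistics report then combines the
measured densities with the drawn stiffness values. A failing stage
marks that subject failed and the pipeline continues.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as bdio
from .fem import MaterialParams, SolverOptions, TissueParams
from .gravity import breast_depth_cm, warp_labels
from .meshing import mesh_from_masks
from .roi import measure_local_density
from .segmentation import segment_breast
from .stats import cohort_report
from .synthetic import CohortConfig, PhantomSpec, generate_phantom, sample_cohort

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "process_subject"]


@dataclass
class PipelineConfig:
    """Configuration for an end-to-end synthetic-cohort run.

    ``target_depth_frac`` positions the ultrasound breast depth between
    the zero-gravity depth (0) and the full-inverse-gravity depth (1);
    a real study would take this value from the ultrasound scan.
    """

    n_subjects: int = 2
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(
        grid_shape=(48, 40, 48), voxel_size_mm=2.5,
        breast_semiaxes_mm=(45.0, 50.0, 45.0), chest_slab_mm=15.0))
    cohort: CohortConfig = field(default_factory=CohortConfig)
    material: MaterialParams = field(default_factory=MaterialParams)
    solver: SolverOptions = field(default_factory=SolverOptions)
    target_edge_mm: float = 10.0
    target_depth_frac: float = 0.5
    gravity: tuple = (0.0, 9.81, 0.0)   # prone direction (+y anterior)
    roi_width_cm: float = 1.0
    roi_height_cm: float = 0.5
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["material"] = {
            "fat": asdict(self.material.fat), "fgt": asdict(self.material.fgt)
        }
        return d


def process_subject(config: PipelineConfig, record: pd.Series, index: int) -> dict:
    """Run every stage for one subject; returns the result row."""
    t0 = time.time()
    timings = {}
    target_density = float(np.clip(record["whole_percent_density"], 1.0, 35.0))
    spec = replace(config.phantom, target_percent_density=target_density,
                   seed=config.seed * 10_000 + index)

    phantom = generate_phantom(spec)
    timings["simulate"] = time.time() - t0

    t = time.time()
    seg = segment_breast(phantom.image, phantom.chest_mask)
    timings["segment"] = time.time() - t

    t = time.time()
    mesh = mesh_from_masks(seg.breast_mask, seg.fgt_mask, phantom.image,
                           phantom.chest_plane_y_mm, phantom.nipple_location_mm,
                           target_edge_mm=config.target_edge_mm)
    timings["mesh"] = time.time() - t

    t = time.time()
    # probe the feasible depth range, then set the per-subject US depth
    from .fem import solve_static
    from .gravity import estimate_zero_gravity, load_supine_until_depth

    g = np.asarray(config.gravity, float)
    rest, residuals = estimate_zero_gravity(mesh, config.material, g, config.solver)
    d0 = breast_depth_cm(rest, mesh.nipple_node, phantom.chest_plane_y_mm)
    full_state = solve_static(mesh, config.material, -g, config.solver,
                              reference_nodes_mm=rest)
    d1 = breast_depth_cm(full_state.current_nodes, mesh.nipple_node,
                         phantom.chest_plane_y_mm)
    target_depth = d1 + config.target_depth_frac * (d0 - d1)
    supine, lam, history, warning = load_supine_until_depth(
        mesh, rest, config.material, -g, target_depth_cm=target_depth,
        chest_plane_y_mm=phantom.chest_plane_y_mm, options=config.solver)
    timings["deform"] = time.time() - t

    t = time.time()
    labels = warp_labels(mesh, mesh.nodes, supine, seg.fgt_mask, seg.breast_mask,
                         phantom.image)
    supine_nipple = supine[mesh.nipple_node]
    roi_depth = float(record["roi_depth"])
    achieved = breast_depth_cm(supine, mesh.nipple_node, phantom.chest_plane_y_mm)
    roi_depth = min(roi_depth, max(0.1, achieved - config.roi_height_cm - 0.3))
    local = measure_local_density(labels, supine_nipple, roi_depth,
                                  config.roi_width_cm, config.roi_height_cm)
    timings["measure"] = time.time() - t

    row = {
        "subject_id": record["subject_id"],
        "age": float(record["age"]),
        "breast_volume": seg.breast_volume_cm3,
        "fgt_volume": seg.fgt_volume_cm3,
        "whole_percent_density": seg.percent_density,
        "local_percent_density": local,
        "stiffness": float(record["stiffness"]),
        "stiffness_repeats": record["stiffness_repeats"],
        "roi_depth": roi_depth,
        "roi_window": record["roi_window"],
        "target_density": target_density,
        "load_factor": lam,
        "depth_target_cm": target_depth,
        "depth_achieved_cm": achieved,
        "zero_g_residual_mm": residuals[-1],
        "status": "ok",
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
    }
    if warning:
        row["depth_warning"] = warning
    return row


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full per-subject pipeline and the cohort statistics.

    Returns a report dict with per-subject rows, failures, the cohort
    statistics over the successfully measured subjects, and provenance.
    Per-subject results are checkpointed to ``out_dir`` (JSON) when one
    is given, and reused on rerun.
    """
    cohort = sample_cohort(config.cohort, n_subjects=config.n_subjects,
                           seed=config.seed)
    out_dir = config.out_dir
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)

    rows, failures = [], []
    for i, (_, record) in enumerate(cohort.iterrows()):
        ckpt = os.path.join(out_dir, f"subject_{i:03d}.json") if out_dir else None
        if ckpt and os.path.exists(ckpt):
            with open(ckpt) as fh:
                row = json.load(fh)
            log.info("subject %d: resumed from checkpoint", i)
        else:
            try:
                row = process_subject(config, record, i)
            except Exception as exc:  # noqa: BLE001 - per-subject isolation
                log.error("subject %d failed: %s", i, exc)
                failures.append({"subject_id": record["subject_id"],
                                 "error": str(exc)})
                continue
            if ckpt:
                with open(ckpt, "w") as fh:
                    json.dump(row, fh, indent=2)
        rows.append(row)

    report: dict = {
        "provenance": bdio.provenance(config.to_dict(), config.seed),
        "n_requested": config.n_subjects,
        "n_ok": len(rows),
        "failures": failures,
        "subjects": rows,
    }
    if len(rows) >= 3:
        df = pd.DataFrame(rows)
        report["cohort_statistics"] = cohort_report(df)
    if out_dir:
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
    return report
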
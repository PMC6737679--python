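"""Prone -> zero-gravity -> supine deformation of the breast mesh.

The MR volume is acquired prone (gravity pulling the breast away from
the chest); the ultrasound is acquired supine. The unloaded (rest)
shape is unknown, so it is estimated by a fixed-point iteration: guess
rest coordinates, simulate prone gravity, and move the guess by the
mismatch against the observed prone shape. From the recovered rest
shape, inverse (supine) gravity is applied with a scalar load factor,
and bisection on that factor stops the deformation when the simulated
breast depth equals the breast depth seen on ultrasound. Finally the
voxel label volume is warped through the mesh displacement field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fem import MaterialParams, SolverOptions, solve_static
from .meshing import LabeledTetMesh
from .volume import ImageVolume

log = logging.getLogger(__name__)

__all__ = [
    "GravityStages",
    "breast_depth_cm",
    "estimate_zero_gravity",
    "load_supine_until_depth",
    "warp_labels",
    "run_gravity_pipeline",
]

BG, FAT_LABEL, FGT_LABEL = 0, 1, 2


@dataclass
class GravityStages:
    """Node coordinates of the three stages over one shared topology."""

    mesh: LabeledTetMesh                    # topology + prone nodes
    prone_nodes: np.ndarray
    zero_gravity_nodes: np.ndarray
    supine_nodes: np.ndarray
    load_factor_at_stop: float
    depths_cm: dict                          # per-stage anterior breast depth
    zero_g_residuals_mm: list = field(default_factory=list)
    bisection_history: list = field(default_factory=list)
    depth_warning: str | None = None


def breast_depth_cm(nodes_mm: np.ndarray, nipple_node: int,
                    chest_plane_y_mm: float, gravity_axis: int = 1,
                    lateral_tol_mm: float = 8.0) -> float:
    """Anterior breast thickness at the nipple line, in cm.

    Distance from the chest plane to the anterior-most node lying
    within ``lateral_tol_mm`` of the nipple's sagittal line (the probe
    geometry of a supine ultrasound exam).
    """
    lateral_axes = [a for a in range(3) if a != gravity_axis]
    nipple = nodes_mm[nipple_node]
    d_lat = np.abs(nodes_mm[:, lateral_axes[0]] - nipple[lateral_axes[0]])
    near = d_lat <= lateral_tol_mm
    if not near.any():
        near = np.ones(len(nodes_mm), bool)
    return float((nodes_mm[near, gravity_axis].max() - chest_plane_y_mm) / 10.0)


def estimate_zero_gravity(mesh: LabeledTetMesh, params: MaterialParams,
                          prone_gravity, options: SolverOptions | None = None,
                          alpha: float = 1.0, tol_mm: float = 0.5,
                          max_iter: int = 20):
    """Recover the unloaded configuration from the observed prone mesh.

    Fixed-point scheme: with candidate rest nodes X_k, simulate prone
    gravity to get x_k and update X_{k+1} = X_k + alpha (X_obs - x_k).
    The step length is halved after three consecutive residual
    increases; the scheme fails below alpha = 0.05. Returns
    ``(rest_nodes_mm, residual_history_mm)``.
    """
    prone_gravity = np.asarray(prone_gravity, float)
    X_obs = mesh.nodes.copy()
    if np.allclose(prone_gravity, 0.0):
        return X_obs, [0.0]
    X = X_obs.copy()
    residuals: list[float] = []
    increases = 0
    x_sim = None
    for it in range(max_iter):
        state = solve_static(mesh, params, prone_gravity, options,
                             reference_nodes_mm=X, initial_nodes_mm=x_sim)
        x_sim = state.current_nodes
        err = X_obs - x_sim
        res = float(np.linalg.norm(err, axis=1).max())
        residuals.append(res)
        log.info("zero-gravity iteration %d: residual %.3f mm (alpha %.2f)",
                 it + 1, res, alpha)
        if res < tol_mm:
            return X, residuals
        if len(residuals) >= 2 and res > residuals[-2]:
            increases += 1
            if increases >= 3:
                alpha *= 0.5
                increases = 0
                if alpha < 0.05:
                    raise RuntimeError(
                        f"zero-gravity estimation diverged (residuals {residuals})"
                    )
        else:
            increases = 0
        X = X + alpha * err
    raise RuntimeError(
        f"zero-gravity estimation did not reach {tol_mm} mm in {max_iter} "
        f"iterations (last residual {residuals[-1]:.3f} mm)"
    )


def load_supine_until_depth(mesh: LabeledTetMesh, rest_nodes_mm: np.ndarray,
                            params: MaterialParams, supine_gravity,
                            target_depth_cm: float,
                            chest_plane_y_mm: float,
                            options: SolverOptions | None = None,
                            depth_tol_cm: float = 0.05,
                            max_bisect: int = 12):
    """Scale supine gravity until the simulated depth matches ultrasound.

    Breast depth decreases monotonically with the supine load factor
    lambda; bisection on lambda in [0, 1] stops within
    ``depth_tol_cm``. If even full inverse gravity leaves the breast
    deeper than the target, lambda = 1 is returned with a warning.
    Returns ``(supine_nodes_mm, load_factor, history, warning)``.
    """
    if mesh.nipple_node is None:
        raise ValueError("mesh has no nipple node; cannot measure depth")
    supine_gravity = np.asarray(supine_gravity, float)
    history: list[tuple[float, float]] = []

    def depth_at(lam: float, init=None):
        if lam == 0.0:
            return rest_nodes_mm.copy(), breast_depth_cm(
                rest_nodes_mm, mesh.nipple_node, chest_plane_y_mm)
        state = solve_static(mesh, params, lam * supine_gravity, options,
                             reference_nodes_mm=rest_nodes_mm,
                             initial_nodes_mm=init)
        d = breast_depth_cm(state.current_nodes, mesh.nipple_node, chest_plane_y_mm)
        return state.current_nodes, d

    nodes0, d0 = depth_at(0.0)
    history.append((0.0, d0))
    if target_depth_cm > d0 + depth_tol_cm:
        raise ValueError(
            f"target depth {target_depth_cm:.2f} cm exceeds the zero-gravity "
            f"depth {d0:.2f} cm"
        )
    if abs(d0 - target_depth_cm) <= depth_tol_cm:
        return nodes0, 0.0, history, None

    nodes1, d1 = depth_at(1.0, init=nodes0)
    history.append((1.0, d1))
    if d1 > target_depth_cm + depth_tol_cm:
        warning = (f"full inverse gravity reaches depth {d1:.2f} cm, short of "
                   f"target {target_depth_cm:.2f} cm; returning lambda = 1")
        log.warning(warning)
        return nodes1, 1.0, history, warning

    lo, hi = 0.0, 1.0
    nodes = nodes1
    for _ in range(max_bisect):
        lam = 0.5 * (lo + hi)
        nodes, d = depth_at(lam, init=nodes)
        history.append((lam, d))
        log.info("bisection: lambda=%.3f depth=%.3f cm (target %.3f)",
                 lam, d, target_depth_cm)
        if abs(d - target_depth_cm) <= depth_tol_cm:
            return nodes, lam, history, None
        if d > target_depth_cm:
            lo = lam   # need more load to flatten further
        else:
            hi = lam
    log.warning("bisection hit iteration cap; closest depth %.3f cm", d)
    return nodes, lam, history, "bisection iteration cap reached"


def warp_labels(mesh: LabeledTetMesh, source_nodes_mm: np.ndarray,
                deformed_nodes_mm: np.ndarray, fgt_mask: np.ndarray,
                breast_mask: np.ndarray, grid: ImageVolume,
                max_unmapped_frac: float = 0.05) -> ImageVolume:
    """Warp the voxel tissue labels through the mesh deformation.

    For each voxel center inside the deformed mesh, the containing
    deformed tetrahedron is found, the point is pulled back to the
    source configuration with its barycentric coordinates, and the
    nearest-neighbour source label is sampled (0 background, 1 fat,
    2 fibroglandular). Raises if more than ``max_unmapped_frac`` of the
    voxels inside the deformed mesh fail to map.
    """
    fgt_mask = np.asarray(fgt_mask, bool)
    breast_mask = np.asarray(breast_mask, bool)
    shape = grid.data.shape
    out = np.zeros(shape, dtype=np.uint8)
    assigned = np.zeros(shape, dtype=bool)

    src_labels = np.zeros(shape, dtype=np.uint8)
    src_labels[breast_mask] = FAT_LABEL
    src_labels[fgt_mask] = FGT_LABEL
    # The mesh surface and the voxel mask disagree by up to a voxel; a
    # pulled-back point is inside the source mesh by construction, so
    # sample the nearest labeled voxel rather than background.
    from scipy import ndimage
    fill_idx = ndimage.distance_transform_edt(
        src_labels == 0, sampling=grid.spacing, return_distances=False,
        return_indices=True)
    src_filled = src_labels[tuple(fill_idx)]

    inv_aff = np.linalg.inv(grid.affine)
    spacing = grid.spacing
    eps = 1e-9

    det_total = 0.0
    for e in range(len(mesh.tets)):
        tet = mesh.tets[e]
        p = deformed_nodes_mm[tet]            # (4, 3)
        lo = grid.world_to_index(p.min(axis=0))
        hi = grid.world_to_index(p.max(axis=0))
        i0 = np.maximum(np.floor(lo).astype(int), 0)
        i1 = np.minimum(np.ceil(hi).astype(int) + 1, shape)
        if np.any(i0 >= i1):
            continue
        ii = np.stack(np.meshgrid(*[np.arange(i0[d], i1[d]) for d in range(3)],
                                  indexing="ij"), axis=-1).reshape(-1, 3)
        centers = grid.index_to_world(ii)
        T = (p[1:] - p[0]).T                  # columns are edges
        det = np.linalg.det(T)
        det_total += abs(det) / 6.0
        if abs(det) < 1e-12:
            continue
        bary = np.linalg.solve(T, (centers - p[0]).T).T   # (n, 3)
        w0 = 1.0 - bary.sum(axis=1)
        inside = (bary >= -eps).all(axis=1) & (w0 >= -eps)
        if not inside.any():
            continue
        src_pts = (np.concatenate([w0[inside, None], bary[inside]], axis=1)
                   @ source_nodes_mm[tet])
        src_idx = np.round(grid.world_to_index(src_pts)).astype(int)
        ok = np.all((src_idx >= 0) & (src_idx < np.array(shape)), axis=1)
        vox = ii[inside]
        out[tuple(vox[ok].T)] = src_filled[tuple(src_idx[ok].T)]
        assigned[tuple(vox[ok].T)] = True

    expected = det_total / grid.voxel_volume_mm3
    n_assigned = int(assigned.sum())
    if expected > 0 and n_assigned < (1.0 - max_unmapped_frac) * expected:
        raise RuntimeError(
            f"only {n_assigned} of ~{expected:.0f} in-breast voxels mapped "
            f"(> {100 * max_unmapped_frac:.0f}% unmapped)"
        )
    return grid.like(out)


def run_gravity_pipeline(mesh: LabeledTetMesh, params: MaterialParams,
                         target_depth_cm: float, chest_plane_y_mm: float,
                         prone_gravity=(0.0, 9.81, 0.0),
                         options: SolverOptions | None = None,
                         zero_g_kwargs: dict | None = None,
                         bisect_kwargs: dict | None = None) -> GravityStages:
    """Prone mesh -> rest shape -> depth-matched supine mesh."""
    prone_gravity = np.asarray(prone_gravity, float)
    supine_gravity = -prone_gravity
    rest, residuals = estimate_zero_gravity(mesh, params, prone_gravity, options,
                                            **(zero_g_kwargs or {}))
    supine, lam, history, warning = load_supine_until_depth(
        mesh, rest, params, supine_gravity, target_depth_cm,
        chest_plane_y_mm, options, **(bisect_kwargs or {}))
    depths = {
        "prone": breast_depth_cm(mesh.nodes, mesh.nipple_node, chest_plane_y_mm),
        "zero_gravity": breast_depth_cm(rest, mesh.nipple_node, chest_plane_y_mm),
        "supine": breast_depth_cm(supine, mesh.nipple_node, chest_plane_y_mm),
    }
    return GravityStages(
        mesh=mesh,
        prone_nodes=mesh.nodes.copy(),
        zero_gravity_nodes=rest,
        supine_nodes=supine,
        load_factor_at_stop=lam,
        depths_cm=depths,
        zero_g_residuals_mm=residuals,
        bisection_history=history,
        depth_warning=warning,
    )
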
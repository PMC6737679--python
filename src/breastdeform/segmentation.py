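"""Breast and fibroglandular-tissue segmentation from T1-weighted volumes.

The stage order mirrors a standard volumetric breast-density workflow:
exclude the chest body region, correct the smooth intensity bias field,
split the remaining breast voxels into fat and fibroglandular classes
with fuzzy C-means on intensity, and report volumes and percent density
(100 x FGT volume / breast volume).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ImageVolume

log = logging.getLogger(__name__)

__all__ = [
    "SegmentationResult",
    "exclude_chest",
    "bias_correct",
    "fuzzy_c_means",
    "compute_density",
    "segment_breast",
]


@dataclass
class SegmentationResult:
    breast_mask: np.ndarray
    fgt_mask: np.ndarray
    breast_volume_cm3: float
    fgt_volume_cm3: float
    percent_density: float
    fcm_centers: np.ndarray | None = None
    fcm_mean_winning_membership: float | None = None
    fcm_converged: bool = True


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("empty foreground: no voxels above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def exclude_chest(image: ImageVolume, chest_mask: np.ndarray | None,
                  background_frac: float = 0.1) -> np.ndarray:
    """Breast mask: thresholded foreground minus the chest body region.

    Foreground is intensity above ``background_frac`` of the robust
    (99th-percentile) maximum, reduced to its largest connected
    component. ``chest_mask`` may be a full 3D mask (phantom ground
    truth or a user-supplied file) or a single middle-sagittal 2D chest
    region, which is then propagated slice by slice superiorly and
    inferiorly, each slice's chest estimate initialized from its
    neighbour and trimmed to the local foreground.
    """
    data = np.asarray(image.data, dtype=float)
    thresh = background_frac * np.percentile(data, 99)
    fg = data > thresh
    if not fg.any():
        raise ValueError("empty foreground: image has no signal above background")
    fg = _largest_component(fg)

    if chest_mask is None:
        chest = np.zeros_like(fg)
    elif chest_mask.ndim == 3:
        chest = chest_mask.astype(bool)
    elif chest_mask.ndim == 2:
        # Propagate the mid-slice chest boundary along the sagittal axis:
        # per lateral column the chest extends up to a boundary depth, and
        # each slice is initialized from its neighbour's boundary.
        chest = np.zeros_like(fg)
        ni, nj, nk = fg.shape
        jj = np.arange(nj)[:, None]

        def boundary_depth(region: np.ndarray) -> np.ndarray:
            depth = np.full(region.shape[1], -1)
            any_col = region.any(axis=0)
            depth[any_col] = nj - 1 - np.argmax(region[::-1], axis=0)[any_col]
            if any_col.any():
                depth[~any_col] = int(np.median(depth[any_col]))
            return depth

        mid = ni // 2
        depth0 = boundary_depth(chest_mask.astype(bool))
        for sweep in (range(mid, ni), range(mid - 1, -1, -1)):
            depth = depth0.copy()
            for i in sweep:
                cur = fg[i] & (jj <= depth[None, :])
                chest[i] = cur
                if cur.any():
                    depth = boundary_depth(cur)
    else:
        raise ValueError("chest_mask must be 2D (mid-slice) or 3D")

    breast = fg & ~chest
    if not breast.any():
        raise ValueError("chest mask covers the entire foreground")
    return _largest_component(breast)


def _poly_design(idx: np.ndarray, shape, degree: int) -> np.ndarray:
    """Polynomial design matrix in coordinates normalized to [-1, 1]."""
    u = 2.0 * idx / (np.asarray(shape, float) - 1) - 1.0
    cols = [np.ones(len(u))]
    for px in range(degree + 1):
        for py in range(degree + 1 - px):
            for pz in range(degree + 1 - px - py):
                if px + py + pz == 0:
                    continue
                cols.append(u[:, 0] ** px * u[:, 1] ** py * u[:, 2] ** pz)
    return np.stack(cols, axis=1)


def bias_correct(image: ImageVolume, mask: np.ndarray, degree: int = 2,
                 n_classes: int = 2, n_outer: int = 5) -> ImageVolume:
    """Remove a smooth multiplicative shading field inside the mask.

    A plain polynomial fit to log-intensity would absorb genuine tissue
    contrast (a central fibroglandular core looks like a dark blob a
    quadratic can fit), so the field estimate is coupled to the tissue
    classification: each outer iteration classifies the current
    corrected intensities with fuzzy C-means, fits a degree-``degree``
    polynomial to the log-residuals relative to each voxel's winning
    class center, and divides the field out. The mask-mean intensity of
    the input is restored at the end, and output intensities are
    strictly positive inside the mask.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    data = np.asarray(image.data, dtype=float)
    inside = data[mask]
    shift = 0.0
    if inside.min() <= 0:
        shift = -inside.min() + 1e-3 * max(float(np.ptp(inside)), 1.0)
        warnings.warn("nonpositive intensities inside mask; shifting before log")
    vals = inside + shift

    idx = np.argwhere(mask)
    A = _poly_design(idx, image.data.shape, degree)
    total_log_field = np.zeros(len(vals))

    current = vals.copy()
    for _ in range(max(1, n_outer)):
        if n_classes >= 2 and np.unique(current).size >= n_classes:
            centers, u, _ = fuzzy_c_means(current, c=n_classes)
            winning = centers[np.argmax(u, axis=1)]
        else:
            winning = np.full_like(current, current.mean())
        resid = np.log(np.maximum(current, 1e-12)) - np.log(np.maximum(winning, 1e-12))
        coef, *_ = np.linalg.lstsq(A, resid, rcond=None)
        log_field = A @ coef
        log_field -= log_field.mean()  # field carries no global gain
        if np.abs(log_field).max() < 1e-4:
            break
        total_log_field += log_field
        current = vals / np.exp(total_log_field)

    corrected = data.astype(float).copy()
    corrected[mask] = current * (inside.mean() / current.mean())
    return image.like(corrected)


def estimate_bias_field(image: ImageVolume, mask: np.ndarray, degree: int = 2) -> np.ndarray:
    """The fitted multiplicative field inside the mask (for validation)."""
    corrected = bias_correct(image, mask, degree=degree)
    with np.errstate(divide="ignore", invalid="ignore"):
        field = np.where(mask, image.data / np.maximum(corrected.data, 1e-12), 1.0)
    return field


def fuzzy_c_means(intensities, c: int = 2, m: float = 2.0, tol: float = 1e-4,
                  max_iter: int = 200, seed: int | None = 0,
                  initial_centers=None):
    """Fuzzy C-means clustering of scalar intensities.

    Alternates the standard membership and center updates
    u_ik = 1 / sum_j (d_ik/d_jk)^(2/(m-1)),  v_k = sum_i u_ik^m x_i / sum_i u_ik^m
    until the largest center shift falls below ``tol`` times the
    intensity range. Centers are initialized at evenly spaced quantiles
    of the data, so the result is deterministic. Returns
    ``(centers, memberships, converged)`` with centers sorted ascending.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if np.unique(x).size < c:
        raise ValueError(f"need at least {c} distinct intensity values")

    if initial_centers is not None:
        centers = np.sort(np.asarray(initial_centers, float))
    else:
        qs = (np.arange(c) + 0.5) / c
        centers = np.quantile(x, qs)
        # quantile ties (heavily skewed data) -> spread across the range
        if np.unique(centers).size < c:
            centers = np.linspace(x.min(), x.max(), c + 2)[1:-1]

    span = max(np.ptp(x), 1e-12)
    exponent = 2.0 / (m - 1.0)
    converged = False
    u = None
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centers[None, :])
        d = np.maximum(d, 1e-12 * span)
        inv = d ** (-exponent)
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u ** m
        new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol * span:
            converged = True
            break
    if not converged:
        warnings.warn("fuzzy C-means did not converge within max_iter")
    order = np.argsort(centers)
    return centers[order], u[:, order], converged


def fcm_objective(x, centers, u, m: float = 2.0) -> float:
    """The FCM cost sum_ik u_ik^m d_ik^2 (monotone non-increasing)."""
    x = np.asarray(x, float).ravel()
    d2 = (x[:, None] - np.asarray(centers)[None, :]) ** 2
    return float((np.asarray(u) ** m * d2).sum())


def compute_density(breast_mask: np.ndarray, fgt_mask: np.ndarray,
                    spacing_mm) -> SegmentationResult:
    """Volumes (cm^3) and whole-breast percent density from label masks."""
    breast_mask = np.asarray(breast_mask, bool)
    fgt_mask = np.asarray(fgt_mask, bool)
    if not breast_mask.any():
        raise ValueError("breast mask is empty")
    if (fgt_mask & ~breast_mask).any():
        raise ValueError("fgt_mask extends outside breast_mask")
    voxel_cm3 = float(np.prod(np.broadcast_to(np.asarray(spacing_mm, float), (3,)))) / 1000.0
    bv = breast_mask.sum() * voxel_cm3
    fv = fgt_mask.sum() * voxel_cm3
    return SegmentationResult(
        breast_mask=breast_mask,
        fgt_mask=fgt_mask,
        breast_volume_cm3=float(bv),
        fgt_volume_cm3=float(fv),
        percent_density=float(100.0 * fv / bv),
    )


def segment_breast(image: ImageVolume, chest_mask: np.ndarray | None,
                   fat_is_bright: bool = True, fcm_kwargs: dict | None = None
                   ) -> SegmentationResult:
    """Full pipeline: chest exclusion, bias correction, FCM, density.

    ``fat_is_bright`` selects the class polarity: on T1-weighted images
    fat is the high-intensity class, so the FGT mask collects voxels
    whose winning membership belongs to the lower-intensity center.
    """
    breast_mask = exclude_chest(image, chest_mask)
    corrected = bias_correct(image, breast_mask)
    vals = corrected.data[breast_mask]
    centers, u, converged = fuzzy_c_means(vals, **(fcm_kwargs or {}))
    winning = np.argmax(u, axis=1)
    fgt_class = 0 if fat_is_bright else len(centers) - 1
    fgt_mask = np.zeros_like(breast_mask)
    fgt_mask[breast_mask] = winning == fgt_class
    result = compute_density(breast_mask, fgt_mask, image.spacing)
    result.fcm_centers = centers
    result.fcm_mean_winning_membership = float(u.max(axis=1).mean())
    result.fcm_converged = converged
    log.info("segmented breast: %.1f cm3, FGT %.1f cm3, density %.1f%%",
             result.breast_volume_cm3, result.fgt_volume_cm3, result.percent_density)
    return result
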
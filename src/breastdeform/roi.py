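"""Ultrasound-equivalent ROI placement and local percent density.

The elastography ROI is reproduced on the deformed (supine) label
volume: a rectangular window on the sagittal slice through the nipple,
centred laterally on the nipple line with its top edge a given depth
below the skin surface along the gravity axis. Local percent density is
the fibroglandular fraction of the whole box (non-breast voxels count
in the denominator, mirroring how the area ratio is read off an
ultrasound window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gravity import FGT_LABEL
from .volume import ImageVolume

__all__ = ["RoiBox", "place_roi", "local_percent_density", "measure_local_density"]


@dataclass(frozen=True)
class RoiBox:
    """Elastography measurement window.

    ``depth_from_skin_cm`` is the skin-to-top-edge distance; ``width_cm``
    spans the lateral (in-slice, non-gravity) axis and ``height_cm`` the
    depth axis. Default window 1.0 x 0.5 cm.
    """

    depth_from_skin_cm: float
    width_cm: float = 1.0
    height_cm: float = 0.5

    def __post_init__(self) -> None:
        if self.depth_from_skin_cm < 0:
            raise ValueError("depth_from_skin_cm must be nonnegative")
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError("ROI window must have positive area")


def place_roi(labels: ImageVolume, nipple_location_mm, roi: RoiBox,
              gravity_axis: int = 1, slice_axis: int = 0) -> tuple:
    """Voxel index set of the ROI box on the nipple slice.

    Returns index arrays (i, j, k) suitable for fancy indexing. The box
    lies on the ``slice_axis`` slice containing the nipple; its top edge
    sits ``depth_from_skin_cm`` below the skin (the most anterior
    labeled voxel on the nipple line) along the gravity axis, and it is
    centred on the nipple line along the remaining lateral axis.
    """
    data = np.asarray(labels.data)
    nip_idx = np.round(labels.world_to_index(np.asarray(nipple_location_mm, float))
                       ).astype(int)
    if np.any(nip_idx < 0) or np.any(nip_idx >= np.array(data.shape)):
        raise ValueError("nipple location outside the volume")
    lat_axis = ({0, 1, 2} - {gravity_axis, slice_axis}).pop()
    spacing = labels.spacing

    s = nip_idx[slice_axis]
    plane = np.take(data, s, axis=slice_axis)
    # axes of `plane`: the two non-slice axes in ascending order
    plane_axes = [a for a in range(3) if a != slice_axis]
    g_in_plane = plane_axes.index(gravity_axis)
    l_in_plane = plane_axes.index(lat_axis)

    # skin: most anterior labeled voxel on the nipple lateral line
    lat_line = np.take(plane, nip_idx[lat_axis], axis=l_in_plane)
    filled = np.nonzero(lat_line > 0)[0]
    if filled.size == 0:
        raise ValueError("no breast tissue on the nipple line of this slice")
    skin = filled.max()

    depth_vox = roi.depth_from_skin_cm * 10.0 / spacing[gravity_axis]
    height_vox = roi.height_cm * 10.0 / spacing[gravity_axis]
    half_width_vox = 0.5 * roi.width_cm * 10.0 / spacing[lat_axis]

    g_top = int(round(skin - depth_vox))
    g_bot = int(round(skin - depth_vox - height_vox))
    l_lo = int(round(nip_idx[lat_axis] - half_width_vox))
    l_hi = int(round(nip_idx[lat_axis] + half_width_vox))

    n_g = plane.shape[g_in_plane]
    n_l = plane.shape[l_in_plane]
    if g_bot < 0 or g_top >= n_g or l_lo < 0 or l_hi >= n_l:
        raise ValueError(
            f"ROI box exceeds the grid: depth rows [{g_bot}, {g_top}], "
            f"lateral cols [{l_lo}, {l_hi}] on a {plane.shape} slice"
        )
    g_rng = np.arange(g_bot, g_top + 1)
    l_rng = np.arange(l_lo, l_hi + 1)
    gg, ll = np.meshgrid(g_rng, l_rng, indexing="ij")

    idx = [None, None, None]
    idx[slice_axis] = np.full(gg.size, s)
    idx[gravity_axis] = gg.ravel()
    idx[lat_axis] = ll.ravel()
    return tuple(idx)


def local_percent_density(labels: ImageVolume, roi_voxels: tuple) -> float:
    """FGT fraction of the ROI box, in percent of the whole box."""
    if len(roi_voxels[0]) == 0:
        raise ValueError("ROI is empty")
    vals = labels.data[roi_voxels]
    return float(100.0 * (vals == FGT_LABEL).sum() / vals.size)


def measure_local_density(labels: ImageVolume, nipple_location_mm,
                          depth_from_skin_cm: float, width_cm: float = 1.0,
                          height_cm: float = 0.5, gravity_axis: int = 1,
                          slice_axis: int = 0) -> float:
    """Place the window and return the local percent density."""
    roi = RoiBox(depth_from_skin_cm, width_cm, height_cm)
    vox = place_roi(labels, nipple_location_mm, roi, gravity_axis, slice_axis)
    return local_percent_density(labels, vox)
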
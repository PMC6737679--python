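"""Zero-gravity estimation, depth-matched supine loading, label warping."""

import numpy as np
import pytest

from breastdeform import (
    MaterialParams,
    breast_depth_cm,
    estimate_zero_gravity,
    load_supine_until_depth,
    solve_static,
    warp_labels,
)
from breastdeform.meshing import LabeledTetMesh

PRONE_G = np.array([0.0, 9.81, 0.0])


class TestZeroGravity:
    def test_no_gravity_returns_input(self, phantom_mesh, materials):
        rest, residuals = estimate_zero_gravity(phantom_mesh, materials,
                                                np.zeros(3))
        assert np.array_equal(rest, phantom_mesh.nodes)
        assert residuals == [0.0]

    def test_round_trip_recovers_rest_shape(self, round_trip, phantom_mesh):
        rest, _ = round_trip
        err = np.linalg.norm(rest - phantom_mesh.nodes, axis=1).max()
        assert err < 0.5

    def test_residuals_strictly_decreasing(self, round_trip):
        _, residuals = round_trip
        assert all(b < a for a, b in zip(residuals, residuals[1:]))

    def test_composition_consistency(self, round_trip, prone_mesh, materials):
        """Simulating prone gravity from the recovered rest shape must
        reproduce the observed prone nodes within the stopping tolerance."""
        rest, _ = round_trip
        state = solve_static(prone_mesh, materials, PRONE_G,
                             reference_nodes_mm=rest)
        err = np.linalg.norm(state.current_nodes - prone_mesh.nodes, axis=1).max()
        assert err < 0.5


class TestSupineLoading:
    def test_target_at_rest_depth_returns_lambda_zero(
            self, round_trip, prone_mesh, phantom, materials):
        rest, _ = round_trip
        d0 = breast_depth_cm(rest, prone_mesh.nipple_node, phantom.chest_plane_y_mm)
        nodes, lam, history, warning = load_supine_until_depth(
            prone_mesh, rest, materials, -PRONE_G, d0, phantom.chest_plane_y_mm)
        assert lam == 0.0 and warning is None
        assert np.array_equal(nodes, rest)

    def test_target_beyond_rest_depth_errors(
            self, round_trip, prone_mesh, phantom, materials):
        rest, _ = round_trip
        d0 = breast_depth_cm(rest, prone_mesh.nipple_node, phantom.chest_plane_y_mm)
        with pytest.raises(ValueError, match="exceeds"):
            load_supine_until_depth(prone_mesh, rest, materials, -PRONE_G,
                                    d0 + 1.0, phantom.chest_plane_y_mm)

    def test_bisection_hits_midway_target(self, round_trip, prone_mesh,
                                          phantom, materials):
        rest, _ = round_trip
        nip = prone_mesh.nipple_node
        y0 = phantom.chest_plane_y_mm
        d0 = breast_depth_cm(rest, nip, y0)
        full = solve_static(prone_mesh, materials, -PRONE_G,
                            reference_nodes_mm=rest)
        d1 = breast_depth_cm(full.current_nodes, nip, y0)
        assert d1 < d0  # supine gravity flattens the breast
        target = 0.5 * (d0 + d1)
        nodes, lam, history, warning = load_supine_until_depth(
            prone_mesh, rest, materials, -PRONE_G, target, y0)
        assert warning is None and 0.0 < lam < 1.0
        assert abs(breast_depth_cm(nodes, nip, y0) - target) <= 0.05

    def test_unreachable_shallow_target_clamps_to_full_load(
            self, round_trip, prone_mesh, phantom, materials):
        rest, _ = round_trip
        nodes, lam, history, warning = load_supine_until_depth(
            prone_mesh, rest, materials, -PRONE_G, 0.5,
            phantom.chest_plane_y_mm)
        assert lam == 1.0 and warning is not None

    def test_depth_monotone_in_load_factor(self, round_trip, prone_mesh,
                                           phantom, materials):
        rest, _ = round_trip
        nip, y0 = prone_mesh.nipple_node, phantom.chest_plane_y_mm
        depths = [breast_depth_cm(rest, nip, y0)]
        init = rest
        for lam in (0.25, 0.5, 0.75, 1.0):
            st = solve_static(prone_mesh, materials, -lam * PRONE_G,
                              reference_nodes_mm=rest, initial_nodes_mm=init)
            init = st.current_nodes
            depths.append(breast_depth_cm(st.current_nodes, nip, y0))
        assert all(b <= a + 1e-6 for a, b in zip(depths, depths[1:]))


class TestWarpLabels:
    def test_identity_deformation_preserves_labels(self, phantom, phantom_mesh):
        out = warp_labels(phantom_mesh, phantom_mesh.nodes, phantom_mesh.nodes,
                          phantom.fgt_mask, phantom.breast_mask, phantom.image)
        src = np.where(phantom.fgt_mask, 2, np.where(phantom.breast_mask, 1, 0))
        both = (out.data > 0) & (src > 0)
        agree = (out.data[both] == src[both]).mean()
        assert agree >= 0.99

    def test_pure_translation_moves_labels_exactly(self, phantom, phantom_mesh):
        shift_vox = np.array([0, -2, 0])  # two voxels posterior
        shift_mm = shift_vox * phantom.image.spacing
        out = warp_labels(phantom_mesh, phantom_mesh.nodes,
                          phantom_mesh.nodes + shift_mm,
                          phantom.fgt_mask, phantom.breast_mask, phantom.image)
        src = np.where(phantom.fgt_mask, 2, np.where(phantom.breast_mask, 1, 0))
        expected = np.roll(src, shift_vox, axis=(0, 1, 2))
        both = (out.data > 0) & (expected > 0)
        assert (out.data[both] == expected[both]).mean() >= 0.99

    def test_supine_warp_conserves_fgt_fraction(self, round_trip, prone_mesh,
                                                phantom, materials):
        rest, _ = round_trip
        st = solve_static(prone_mesh, materials, -PRONE_G,
                          reference_nodes_mm=rest)
        out = warp_labels(prone_mesh, prone_mesh.nodes, st.current_nodes,
                          phantom.fgt_mask, phantom.breast_mask, phantom.image)
        prone_frac = phantom.fgt_mask.sum() / phantom.breast_mask.sum()
        warped_breast = out.data > 0
        warped_frac = (out.data == 2).sum() / warped_breast.sum()
        assert abs(100 * warped_frac - 100 * prone_frac) <= 3.0

    def test_supine_warp_conserves_breast_volume(self, round_trip, prone_mesh,
                                                 phantom, materials):
        """The rasterized warped labels fill the deformed mesh volume."""
        rest, _ = round_trip
        st = solve_static(prone_mesh, materials, -PRONE_G,
                          reference_nodes_mm=rest)
        out = warp_labels(prone_mesh, prone_mesh.nodes, st.current_nodes,
                          phantom.fgt_mask, phantom.breast_mask, phantom.image)
        p = st.current_nodes[prone_mesh.tets]
        supine_vol = (np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0).sum()
        warped_vol = (out.data > 0).sum() * phantom.image.voxel_volume_mm3
        assert abs(warped_vol - supine_vol) / supine_vol < 0.03
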
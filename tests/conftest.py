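"""Shared fixtures.

Expensive artifacts (phantom, mesh, FEM solves, the n=5000 cohort) are
session-scoped so the unit suite and the acceptance suite reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

from breastdeform import (
    CohortConfig,
    MaterialParams,
    PhantomSpec,
    SolverOptions,
    TissueParams,
    box_mesh,
    cohort_report,
    generate_phantom,
    mesh_from_masks,
    sample_cohort,
    solve_static,
)
from breastdeform.meshing import LabeledTetMesh

PRONE_G = np.array([0.0, 9.81, 0.0])


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    # desk-scale phantom: ~212 cm^3 hemiellipsoid on a 2.5 mm grid
    return PhantomSpec(grid_shape=(48, 40, 48), voxel_size_mm=2.5,
                       breast_semiaxes_mm=(45.0, 50.0, 45.0),
                       chest_slab_mm=15.0, seed=3)


@pytest.fixture(scope="session")
def phantom(phantom_spec):
    return generate_phantom(phantom_spec)


@pytest.fixture(scope="session")
def phantom_mesh(phantom) -> LabeledTetMesh:
    return mesh_from_masks(phantom.breast_mask, phantom.fgt_mask, phantom.image,
                           phantom.chest_plane_y_mm, phantom.nipple_location_mm,
                           target_edge_mm=9.0)


@pytest.fixture(scope="session")
def materials() -> MaterialParams:
    return MaterialParams()


@pytest.fixture(scope="session")
def prone_state(phantom_mesh, materials):
    """Converged prone-gravity equilibrium of the phantom mesh."""
    return solve_static(phantom_mesh, materials, PRONE_G)


@pytest.fixture(scope="session")
def prone_mesh(phantom_mesh, prone_state) -> LabeledTetMesh:
    """The phantom mesh re-posed at its simulated prone configuration."""
    return LabeledTetMesh(prone_state.current_nodes, phantom_mesh.tets,
                          phantom_mesh.tissue_label, phantom_mesh.fixed_mask,
                          phantom_mesh.nipple_node)


@pytest.fixture(scope="session")
def column():
    """Slender soft column fixed at its base (analytic verification)."""
    mesh = box_mesh([10.0, 10.0, 100.0], [2, 2, 10])
    mesh.fixed_mask = mesh.nodes[:, 2] < 1e-9
    params = MaterialParams(fat=TissueParams(K=3400.0, nu=0.3),
                            fgt=TissueParams(K=50000.0, nu=0.3))
    return mesh, params


@pytest.fixture(scope="session")
def round_trip(prone_mesh, materials):
    """Recover the rest shape from the simulated prone configuration."""
    from breastdeform import estimate_zero_gravity

    rest, residuals = estimate_zero_gravity(prone_mesh, materials, PRONE_G)
    return rest, residuals


@pytest.fixture(scope="session")
def default_cohort():
    """The n=5000 default-configured cohort at the documented seed."""
    return sample_cohort(CohortConfig(n_subjects=5000, seed=1))


@pytest.fixture(scope="session")
def default_cohort_report(default_cohort):
    return cohort_report(default_cohort)
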
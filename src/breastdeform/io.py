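"""File formats: NIfTI volumes, legacy-VTK meshes, YAML configuration.

Meshes are written as ASCII legacy VTK unstructured grids (tissue label
as cell data, fixed flag and optional displacement as point data) so
any VTK-aware viewer can load the deformation stages.
"""

from __future__ import annotations

import hashlib
import json
import os

import nibabel as nib
import numpy as np
import yaml

from .meshing import LabeledTetMesh
from .volume import ImageVolume

__all__ = [
    "read_volume",
    "write_volume",
    "write_mesh_vtk",
    "write_tetgen",
    "load_yaml",
    "save_yaml",
    "provenance",
]


def read_volume(path) -> ImageVolume:
    path = os.fspath(path)
    if not (path.endswith(".nii") or path.endswith(".nii.gz")):
        raise ValueError(f"unsupported volume format: {path}")
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    return ImageVolume(data, np.asarray(img.affine))


def write_volume(vol: ImageVolume, path) -> None:
    path = os.fspath(path)
    if not (path.endswith(".nii") or path.endswith(".nii.gz")):
        raise ValueError(f"unsupported volume format: {path}")
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, vol.affine), path)


def write_mesh_vtk(mesh: LabeledTetMesh, path,
                   displacements_mm: np.ndarray | None = None) -> None:
    """ASCII legacy VTK unstructured grid (tet cells)."""
    lines = [
        "# vtk DataFile Version 3.0",
        "breastdeform labeled tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(mesh.nodes)} double",
    ]
    lines += [" ".join(f"{c:.8g}" for c in p) for p in mesh.nodes]
    lines.append(f"CELLS {len(mesh.tets)} {5 * len(mesh.tets)}")
    lines += ["4 " + " ".join(str(i) for i in tet) for tet in mesh.tets]
    lines.append(f"CELL_TYPES {len(mesh.tets)}")
    lines += ["10"] * len(mesh.tets)
    lines.append(f"CELL_DATA {len(mesh.tets)}")
    lines.append("SCALARS tissue_label int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(l)) for l in mesh.tissue_label]
    lines.append(f"POINT_DATA {len(mesh.nodes)}")
    lines.append("SCALARS fixed int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(f)) for f in mesh.fixed_mask]
    if displacements_mm is not None:
        lines.append("VECTORS displacement double")
        lines += [" ".join(f"{c:.8g}" for c in d) for d in displacements_mm]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_tetgen(mesh: LabeledTetMesh, basename) -> None:
    """TetGen-style .node / .ele pair (1-based indices)."""
    with open(f"{basename}.node", "w") as fh:
        fh.write(f"{len(mesh.nodes)} 3 0 0\n")
        for i, p in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {p[0]:.8g} {p[1]:.8g} {p[2]:.8g}\n")
    with open(f"{basename}.ele", "w") as fh:
        fh.write(f"{len(mesh.tets)} 4 1\n")
        for i, (tet, lab) in enumerate(zip(mesh.tets, mesh.tissue_label), start=1):
            fh.write(f"{i} {tet[0] + 1} {tet[1] + 1} {tet[2] + 1} {tet[3] + 1} {int(lab)}\n")


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def provenance(config: dict, seed: int) -> dict:
    """Provenance header attached to pipeline outputs."""
    from . import __version__

    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return {"version": __version__, "config_sha256": digest, "seed": int(seed)}
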
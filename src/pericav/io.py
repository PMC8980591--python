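"""File output: legacy-VTK meshes and grids, label tables, YAML configs.

The unstructured quad mesh and the structured fluid grid are written as
ASCII legacy VTK (readable by ParaView and meshio); ROI labels go out as
integer cell data with a TSV sidecar mapping ids to names.
"""

from __future__ import annotations

import os

import numpy as np
import yaml

from pericav.fluid import FluidGrid
from pericav.geometry import QuadMesh

__all__ = ["write_vtk_mesh", "write_vtk_grid", "write_label_table",
           "save_config", "load_config"]


def write_vtk_mesh(path: str, mesh: QuadMesh,
                   cell_data: dict | None = None) -> None:
    """Write a quad mesh as legacy ASCII VTK with optional cell data.

    ROI labels are encoded as integer cell data (``roi_id``); call
    :func:`write_label_table` for the id-to-name sidecar.
    """
    labels = sorted({r for r in mesh.element_region if r})
    label_id = {r: i + 1 for i, r in enumerate(labels)}
    mats = sorted(set(mesh.element_material))
    mat_id = {m: i for i, m in enumerate(mats)}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("pericav paired brain-slice mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.node_coordinates:
            fh.write(f"{x:.10e} {y:.10e} 0.0\n")
        E = mesh.n_elements
        fh.write(f"CELLS {E} {5 * E}\n")
        for quad in mesh.element_connectivity:
            fh.write("4 " + " ".join(str(int(n)) for n in quad) + "\n")
        fh.write(f"CELL_TYPES {E}\n")
        fh.write("9\n" * E)                        # VTK_QUAD
        fh.write(f"CELL_DATA {E}\n")
        fh.write("SCALARS roi_id int 1\nLOOKUP_TABLE default\n")
        for r in mesh.element_region:
            fh.write(f"{label_id.get(r, 0)}\n")
        fh.write("SCALARS material_id int 1\nLOOKUP_TABLE default\n")
        for m in mesh.element_material:
            fh.write(f"{mat_id[m]}\n")
        for name, values in (cell_data or {}).items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for v in np.asarray(values, dtype=float):
                fh.write(f"{v:.10e}\n")


def write_label_table(path: str, mesh: QuadMesh) -> None:
    """TSV sidecar: roi_id -> label name (0 is unlabeled brain)."""
    labels = sorted({r for r in mesh.element_region if r})
    with open(path, "w") as fh:
        fh.write("roi_id\tlabel\n0\t(unlabeled)\n")
        for i, r in enumerate(labels):
            fh.write(f"{i + 1}\t{r}\n")


def write_vtk_grid(path: str, grid: FluidGrid) -> None:
    """Write the fluid grid (cell fields) as legacy ASCII VTK structured points."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("pericav ALE fluid grid\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {grid.nx + 1} {grid.ny + 1} 1\n")
        fh.write(f"ORIGIN {grid.x0:.10e} {grid.y0:.10e} 0.0\n")
        fh.write(f"SPACING {grid.dx:.10e} {grid.dx:.10e} 1.0\n")
        n = grid.nx * grid.ny
        fh.write(f"CELL_DATA {n}\n")
        for name, field in (("vf_csf", grid.vf_csf),
                            ("density", grid.bulk_density()),
                            ("pressure", grid.pressure())):
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for v in field.T.ravel():              # VTK is x-fastest
                fh.write(f"{v:.10e}\n")


def save_config(path: str, config) -> None:
    """Serialize a RunConfig to YAML (lossless round trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path: str):
    from pericav.pipeline import RunConfig

    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))
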
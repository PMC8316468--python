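"""Export and checkpointing.

Meshes and fields go out in plain-text formats readable by ParaView and
standard mesh tools: legacy ASCII VTK (structured points for lattice
fields, polydata for membranes and spring networks) and OFF for bare
meshes.  Cell-state checkpoints (vertex positions, spring connectivity and
rest lengths) are stored in HDF5.
"""

from __future__ import annotations

import numpy as np

from .mesh import TriangleMesh

__all__ = [
    "write_vtk_structured", "write_vtk_polydata", "write_vtk_springs",
    "write_off", "read_off", "save_checkpoint", "load_checkpoint",
]


def write_vtk_structured(path, fields: dict, dx: float) -> None:
    """Legacy-VTK structured-points file with named scalar/vector fields.

    Every field is an (nx, ny, nz) scalar or (nx, ny, nz, 3) vector array;
    the voxel origin is at (dx/2, dx/2, dx/2).
    """
    shape = None
    for v in fields.values():
        shape = v.shape[:3]
        break
    if shape is None:
        raise ValueError("no fields to write")
    nx, ny, nz = shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncellsqueeze field\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {dx / 2} {dx / 2} {dx / 2}\n")
        fh.write(f"SPACING {dx} {dx} {dx}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            arr = np.asarray(arr)
            flat = arr.transpose(2, 1, 0, *range(3, arr.ndim)).reshape(
                nx * ny * nz, -1)
            if flat.shape[1] == 1:
                fh.write(f"SCALARS {name} double\nLOOKUP_TABLE default\n")
                np.savetxt(fh, flat, fmt="%.9g")
            elif flat.shape[1] == 3:
                fh.write(f"VECTORS {name} double\n")
                np.savetxt(fh, flat, fmt="%.9g")
            else:
                raise ValueError(f"field {name} is neither scalar nor 3-vector")


def write_vtk_polydata(path, mesh: TriangleMesh,
                       point_data: dict | None = None) -> None:
    """Legacy-VTK polydata export of a membrane with per-vertex scalars."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncellsqueeze membrane\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        np.savetxt(fh, mesh.X, fmt="%.9g")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        np.savetxt(fh, np.column_stack(
            [np.full(mesh.n_faces, 3), mesh.faces]), fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr[:, None], fmt="%.9g")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.9g")


def write_vtk_springs(path, P0: np.ndarray, P1: np.ndarray) -> None:
    """Spring network as VTK line polydata (one line per spring)."""
    n = len(P0)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncellsqueeze springs\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {2 * n} double\n")
        np.savetxt(fh, np.vstack([P0, P1]), fmt="%.9g")
        fh.write(f"LINES {n} {3 * n}\n")
        np.savetxt(fh, np.column_stack(
            [np.full(n, 2), np.arange(n), np.arange(n) + n]), fmt="%d")


def write_off(path, mesh: TriangleMesh) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        np.savetxt(fh, mesh.X, fmt="%.12g")
        np.savetxt(fh, np.column_stack(
            [np.full(mesh.n_faces, 3), mesh.faces]), fmt="%d")


def read_off(path) -> TriangleMesh:
    with open(path) as fh:
        tokens = fh.read().split()
    if tokens[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    data = np.array(tokens[4:4 + 3 * nv], dtype=float).reshape(nv, 3)
    rest = np.array(tokens[4 + 3 * nv:4 + 3 * nv + 4 * nf], dtype=int)
    faces = rest.reshape(nf, 4)[:, 1:]
    return TriangleMesh(data, faces)


def save_checkpoint(path, cell, step: int = 0, time: float = 0.0) -> None:
    """HDF5 checkpoint of one cell (positions, connectivity, springs)."""
    import h5py
    with h5py.File(path, "w") as f:
        f.attrs["step"] = step
        f.attrs["time"] = time
        go = f.create_group("outer")
        go["X"] = cell.outer.X
        go["X_ref"] = cell.outer.X_ref
        go["faces"] = cell.outer.faces
        if cell.nucleus is not None:
            gn = f.create_group("nucleus")
            gn["X"] = cell.nucleus.X
            gn["X_ref"] = cell.nucleus.X_ref
            gn["faces"] = cell.nucleus.faces
        if cell.springs is not None:
            gs = f.create_group("springs")
            for name in ("src_mem", "src", "tgt_mem", "tgt", "L0", "k",
                         "src_area"):
                gs[name] = getattr(cell.springs, name)
            gs.attrs["E"] = cell.springs.E
            gs.attrs["n_cyto"] = cell.springs.n_cyto


def load_checkpoint(path, cell) -> dict:
    """Restore vertex positions and spring state into ``cell``; returns
    the stored metadata (step, time)."""
    import h5py
    with h5py.File(path, "r") as f:
        cell.outer.X = f["outer/X"][()]
        cell.outer.X_ref = f["outer/X_ref"][()]
        if cell.nucleus is not None and "nucleus" in f:
            cell.nucleus.X = f["nucleus/X"][()]
            cell.nucleus.X_ref = f["nucleus/X_ref"][()]
        if cell.springs is not None and "springs" in f:
            for name in ("src_mem", "src", "tgt_mem", "tgt", "L0", "k",
                         "src_area"):
                setattr(cell.springs, name, f["springs/" + name][()])
        return dict(f.attrs)
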
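"""Text-format writers: ASCII STL, legacy-ASCII VTK, CSV series, HDF5 checkpoints."""

from __future__ import annotations

import numpy as np

__all__ = ["write_stl", "write_vtk_surface", "write_vtk_rectilinear",
           "write_series_csv", "save_checkpoint", "load_checkpoint"]


def write_stl(mesh, path, name: str = "swimmer") -> None:
    """Write a triangulated surface as ASCII STL."""
    v = mesh.vertices[mesh.triangles]          # (M, 3, 3)
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)
    with open(path, "w") as fh:
        fh.write(f"solid {name}\n")
        for tri, nv in zip(v, n):
            fh.write(f" facet normal {nv[0]:.9e} {nv[1]:.9e} {nv[2]:.9e}\n")
            fh.write("  outer loop\n")
            for p in tri:
                fh.write(f"   vertex {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
            fh.write("  endloop\n endfacet\n")
        fh.write(f"endsolid {name}\n")


def write_vtk_surface(mesh, path, point_data: dict = None) -> None:
    """Write a tagged triangle surface as legacy ASCII VTK POLYDATA.

    Region tags go to CELL_DATA; optional per-vertex arrays (e.g.
    deformation velocities) to POINT_DATA.
    """
    verts, tris = mesh.vertices, mesh.triangles
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nswimmer surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(verts)} double\n")
        for p in verts:
            fh.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        fh.write(f"POLYGONS {len(tris)} {4 * len(tris)}\n")
        for t in tris:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"CELL_DATA {len(tris)}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(t)) for t in mesh.tags) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {len(verts)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    for p in arr:
                        fh.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{x:.9e}" for x in arr) + "\n")


def write_vtk_rectilinear(state, path, fields: dict = None) -> None:
    """Write a flow snapshot as legacy ASCII VTK RECTILINEAR_GRID.

    Cell-centre coordinates; velocities interpolated to centres plus any
    extra scalar fields (vorticity, Q, pressure ...).
    """
    from .solver import center_velocity
    nx, ny, h = state.nx, state.ny, state.h
    uc, vc = center_velocity(state)
    xs = (np.arange(nx) + 0.5) * h
    ys = (np.arange(ny) + 0.5) * h
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nflow snapshot\nASCII\n")
        fh.write("DATASET RECTILINEAR_GRID\n")
        fh.write(f"DIMENSIONS {nx} {ny} 1\n")
        fh.write(f"X_COORDINATES {nx} double\n" + " ".join(f"{x:.9e}" for x in xs) + "\n")
        fh.write(f"Y_COORDINATES {ny} double\n" + " ".join(f"{y:.9e}" for y in ys) + "\n")
        fh.write("Z_COORDINATES 1 double\n0.0\n")
        fh.write(f"POINT_DATA {nx * ny}\n")
        fh.write("VECTORS velocity double\n")
        for j in range(ny):
            for i in range(nx):
                fh.write(f"{uc[i, j]:.9e} {vc[i, j]:.9e} 0.0\n")
        fh.write("SCALARS pressure double 1\nLOOKUP_TABLE default\n")
        for j in range(ny):
            for i in range(nx):
                fh.write(f"{state.p[i, j]:.9e}\n")
        for name, arr in (fields or {}).items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for j in range(ny):
                for i in range(nx):
                    fh.write(f"{arr[i, j]:.9e}\n")


def write_series_csv(series, path) -> None:
    """Propulsion time series as CSV with documented column names."""
    import pandas as pd
    pd.DataFrame({
        "t_cycles": series.t, "u_a": series.u_a, "net_force": series.force,
        "thrust": series.thrust, "drag": series.drag, "power": series.power,
        "power_deform": series.power_deform, "distance_bl": series.distance,
    }).to_csv(path, index=False)


def save_checkpoint(state, path) -> None:
    """Flow-state checkpoint as HDF5."""
    import h5py
    with h5py.File(path, "w") as fh:
        for k in ("u", "v", "p"):
            fh.create_dataset(k, data=getattr(state, k))
        for k in ("nx", "ny", "h", "lx", "ly", "nu", "t", "inflow", "lid"):
            fh.attrs[k] = getattr(state, k)
        fh.attrs["bc"] = state.bc


def load_checkpoint(path):
    """Restore a flow state written by :func:`save_checkpoint`."""
    import h5py
    from .solver import FlowState
    with h5py.File(path, "r") as fh:
        state = FlowState(
            nx=int(fh.attrs["nx"]), ny=int(fh.attrs["ny"]), h=float(fh.attrs["h"]),
            lx=float(fh.attrs["lx"]), ly=float(fh.attrs["ly"]),
            nu=float(fh.attrs["nu"]), bc=str(fh.attrs["bc"]),
            u=fh["u"][...], v=fh["v"][...], p=fh["p"][...],
            t=float(fh.attrs["t"]), inflow=float(fh.attrs["inflow"]),
            lid=float(fh.attrs["lid"]))
    return state
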
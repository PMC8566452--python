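"""Legacy (ASCII) VTK writers and minimal readers.

The cell surface goes out as POLYDATA (points, triangle cells, optional
point-data vectors such as velocity); fluid fields as STRUCTURED_POINTS
with a VECTORS velocity array. Both load directly in ParaView and other
standard VTK readers.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "write_cell_vtk",
    "write_fluid_vtk",
    "read_polydata_points",
    "read_structured_points",
]


def write_cell_vtk(path, points, faces, point_vectors=None, vector_name="velocity"):
    points = np.asarray(points, dtype=float)
    faces = np.asarray(faces, dtype=int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncell surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
        fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        for a, b, c in faces:
            fh.write(f"3 {a} {b} {c}\n")
        if point_vectors is not None:
            v = np.asarray(point_vectors, dtype=float)
            fh.write(f"POINT_DATA {len(points)}\n")
            fh.write(f"VECTORS {vector_name} double\n")
            for row in v:
                fh.write(f"{row[0]:.10g} {row[1]:.10g} {row[2]:.10g}\n")


def write_fluid_vtk(path, velocity, spacing, origin=(0.0, 0.0, 0.0)):
    """``velocity``: (3, nx, ny, nz) array (any units, written as given)."""
    v = np.asarray(velocity, dtype=float)
    _, nx, ny, nz = v.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfluid velocity\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]:.10g} {origin[1]:.10g} {origin[2]:.10g}\n")
        fh.write(f"SPACING {spacing:.10g} {spacing:.10g} {spacing:.10g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write("VECTORS velocity double\n")
        for k in range(nz):  # VTK structured order: x fastest
            for j in range(ny):
                for i in range(nx):
                    fh.write(
                        f"{v[0, i, j, k]:.10g} {v[1, i, j, k]:.10g} "
                        f"{v[2, i, j, k]:.10g}\n"
                    )


def _tokens(path):
    with open(path) as fh:
        for line in fh:
            yield from line.split()


def read_polydata_points(path):
    """(points, faces) back from a legacy POLYDATA file (round-trip check)."""
    it = iter(open(path).read().split("\n"))
    points, faces = None, None
    lines = list(it)
    i = 0
    while i < len(lines):
        t = lines[i].split()
        if t and t[0] == "POINTS":
            n = int(t[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals += [float(x) for x in lines[i].split()]
                i += 1
            points = np.array(vals).reshape(n, 3)
            continue
        if t and t[0] == "POLYGONS":
            m = int(t[1])
            rows = []
            i += 1
            for _ in range(m):
                parts = [int(x) for x in lines[i].split()]
                rows.append(parts[1:])
                i += 1
            faces = np.array(rows, dtype=int)
            continue
        i += 1
    return points, faces


def read_structured_points(path):
    """(dims, origin, spacing, velocity) from a legacy STRUCTURED_POINTS file."""
    lines = open(path).read().split("\n")
    dims = origin = spacing = None
    vel = None
    i = 0
    while i < len(lines):
        t = lines[i].split()
        if t and t[0] == "DIMENSIONS":
            dims = tuple(int(x) for x in t[1:4])
        elif t and t[0] == "ORIGIN":
            origin = tuple(float(x) for x in t[1:4])
        elif t and t[0] == "SPACING":
            spacing = float(t[1])
        elif t and t[0] == "VECTORS":
            nx, ny, nz = dims
            vals = []
            i += 1
            while i < len(lines) and len(vals) < 3 * nx * ny * nz:
                vals += [float(x) for x in lines[i].split()]
                i += 1
            arr = np.array(vals).reshape(nz, ny, nx, 3)
            vel = np.moveaxis(arr, (0, 1, 2, 3), (3, 2, 1, 0))
            continue
        i += 1
    return dims, origin, spacing, vel
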
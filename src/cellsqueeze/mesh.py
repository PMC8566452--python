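"""Closed triangulated surface meshes of cells and their rest-state geometry.

A cell membrane is a closed, outward-oriented triangulation. Edges carry
the spring/dashpot elements, triangle pairs the bending elements, triangles
the local-area elements, and the whole surface the global area and volume
constraints; this module computes every geometric quantity those force laws
need, both for the rest (reference) shape and for a deformed configuration.

Lengths are in µm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from . import _kernels

__all__ = [
    "TriMesh",
    "RestState",
    "GeometryState",
    "MeshError",
    "build_icosphere",
    "build_sphere_mesh",
    "build_biconcave_mesh",
    "compute_rest_state",
    "geometry_queries",
    "load_mesh",
    "save_mesh",
]

ICOSPHERE_COUNTS = {12: 0, 42: 1, 162: 2, 642: 3, 2562: 4}


class MeshError(ValueError):
    """Raised for non-manifold, inverted or otherwise invalid meshes."""


@dataclass
class TriMesh:
    """Closed orientable triangulated surface.

    Attributes
    ----------
    points : (N, 3) float array of node positions in µm.
    faces : (F, 3) int array of outward-oriented vertex triples.
    edges : (E, 2) int array, each edge shared by exactly two triangles.
    edge_faces : (E, 2) int array of the two incident triangle indices; the
        first triangle contains the directed edge ``edges[e]`` in its
        winding order.
    edge_apex : (E, 2) int array of the vertex opposite the edge in each
        incident triangle.
    """

    points: np.ndarray
    faces: np.ndarray
    edges: np.ndarray = field(init=False)
    edge_faces: np.ndarray = field(init=False)
    edge_apex: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise MeshError("points must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (F, 3) array")
        self._build_edges()
        self._check_closed()

    # -- topology -----------------------------------------------------------
    def _build_edges(self) -> None:
        emap: dict[tuple[int, int], list] = {}
        for t, (a, b, c) in enumerate(self.faces):
            for u, v, w in ((a, b, c), (b, c, a), (c, a, b)):
                key = (min(u, v), max(u, v))
                rec = emap.setdefault(key, [])
                rec.append((t, int(u), int(v), int(w)))
        edges, efaces, eapex = [], [], []
        for key, rec in sorted(emap.items()):
            if len(rec) != 2:
                raise MeshError(
                    f"edge {key} belongs to {len(rec)} triangle(s); "
                    "mesh is not a closed 2-manifold"
                )
            (t1, u1, v1, w1), (t2, u2, v2, w2) = rec
            if u1 == u2:
                raise MeshError(
                    f"edge {key} has the same direction in triangles "
                    f"{t1} and {t2}; inconsistent orientation"
                )
            edges.append((u1, v1))
            efaces.append((t1, t2))
            eapex.append((w1, w2))
        self.edges = np.ascontiguousarray(edges, dtype=np.int64)
        self.edge_faces = np.ascontiguousarray(efaces, dtype=np.int64)
        self.edge_apex = np.ascontiguousarray(eapex, dtype=np.int64)

    def _check_closed(self) -> None:
        V = self.points.shape[0]
        E = self.edges.shape[0]
        F = self.faces.shape[0]
        if V - E + F != 2:
            raise MeshError(
                f"Euler characteristic V-E+F = {V - E + F} != 2 "
                f"(V={V}, E={E}, F={F})"
            )
        if _kernels.signed_volume(self.points, self.faces) <= 0.0:
            raise MeshError("signed volume is not positive; normals not outward")

    # -- convenience --------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    def surface_area(self, positions: np.ndarray | None = None) -> float:
        pos = self.points if positions is None else positions
        areas, _, _, _ = _kernels.triangle_geometry(pos, self.faces)
        return float(areas.sum())

    def volume(self, positions: np.ndarray | None = None) -> float:
        pos = self.points if positions is None else positions
        return float(_kernels.signed_volume(pos, self.faces))


@dataclass(frozen=True)
class RestState:
    """Reference geometry entering every membrane force law."""

    edge_lengths: np.ndarray  # L0, µm per edge
    dihedrals: np.ndarray  # θ0, radians per edge
    triangle_areas: np.ndarray  # S0_ABC, µm² per triangle
    area: float  # S0, µm²
    volume: float  # V0, µm³


@dataclass(frozen=True)
class GeometryState:
    """Instantaneous geometric quantities of a (possibly deformed) mesh."""

    stretches: np.ndarray  # λ = L/L0 per edge
    dihedrals: np.ndarray  # θ per edge
    triangle_areas: np.ndarray
    triangle_normals: np.ndarray
    triangle_centroids: np.ndarray
    centroid_dist_sq: np.ndarray  # t_a² + t_b² + t_c² per triangle
    area: float
    volume: float
    degenerate_triangles: np.ndarray  # bool per triangle


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        (-1, _ICO_T, 0), (1, _ICO_T, 0), (-1, -_ICO_T, 0), (1, -_ICO_T, 0),
        (0, -1, _ICO_T), (0, 1, _ICO_T), (0, -1, -_ICO_T), (0, 1, -_ICO_T),
        (_ICO_T, 0, -1), (_ICO_T, 0, 1), (-_ICO_T, 0, -1), (-_ICO_T, 0, 1),
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int64,
)


def build_icosphere(radius: float, subdivisions: int = 0) -> TriMesh:
    """Icosahedron subdivided ``subdivisions`` times, projected to a sphere.

    Node counts: 12, 42, 162, 642, 2562 for levels 0–4.
    """
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS[0])
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key in cache:
                return cache[key]
            m = vlist[i] + vlist[j]
            m = m / np.linalg.norm(m)
            vlist.append(m)
            cache[key] = len(vlist) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab = midpoint(a, b)
            bc = midpoint(b, c)
            ca = midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.int64)
    return TriMesh(points=verts * radius, faces=faces)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / golden
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _orient_outward(points: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip triangle windings so all normals point away from the centroid."""
    ctr = points.mean(axis=0)
    out = faces.copy()
    for k, (a, b, c) in enumerate(faces):
        n = np.cross(points[b] - points[a], points[c] - points[a])
        if np.dot(n, (points[a] + points[b] + points[c]) / 3.0 - ctr) < 0.0:
            out[k] = (a, c, b)
    return out


def build_sphere_mesh(radius: float, target_node_count: int) -> TriMesh:
    """Quasi-uniform closed triangulation of a sphere.

    Uses an icosphere when the target is an icosphere count (best
    uniformity), otherwise a Fibonacci lattice triangulated by its convex
    hull, which hits the target node count exactly (covering, e.g., the
    393-node cell discretization).
    """
    if radius <= 0.0:
        raise ValueError("radius must be positive")
    if target_node_count < 12:
        raise ValueError("target_node_count must be at least 12")
    if target_node_count in ICOSPHERE_COUNTS:
        return build_icosphere(radius, ICOSPHERE_COUNTS[target_node_count])
    pts = _fibonacci_sphere(target_node_count)
    hull = ConvexHull(pts)
    faces = _orient_outward(pts, np.ascontiguousarray(hull.simplices, dtype=np.int64))
    return TriMesh(points=pts * radius, faces=faces)


def build_biconcave_mesh(radius: float = 3.91, target_node_count: int = 374) -> TriMesh:
    """Biconcave discoid (red-blood-cell shape), Evans–Fung parameterization.

    A sphere triangulation is mapped radially in z onto
    z(ρ) = ±(R/2)·√(1−ρ²)·(c0 + c1 ρ² + c2 ρ⁴) with the standard
    coefficients c0 = 0.207, c1 = 2.003, c2 = −1.123 and ρ the scaled
    in-plane radius. ``radius`` is the discoid in-plane radius in µm.
    """
    sphere = build_sphere_mesh(1.0, target_node_count)
    p = sphere.points
    rho = np.sqrt(p[:, 0] ** 2 + p[:, 1] ** 2).clip(max=1.0)
    c0, c1, c2 = 0.207, 2.003, -1.123
    zmag = 0.5 * np.sqrt(np.maximum(0.0, 1.0 - rho**2)) * (
        c0 + c1 * rho**2 + c2 * rho**4
    )
    pts = np.column_stack([p[:, 0], p[:, 1], np.sign(p[:, 2]) * zmag]) * radius
    return TriMesh(points=pts, faces=sphere.faces)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def compute_rest_state(mesh: TriMesh) -> RestState:
    """Rest lengths, dihedrals, areas and volume of a mesh's reference shape."""
    areas, _, _, _ = _kernels.triangle_geometry(mesh.points, mesh.faces)
    bad = np.where(areas <= 0.0)[0]
    if bad.size:
        raise MeshError(f"degenerate triangle(s) at rest: {bad.tolist()}")
    L0 = _kernels.edge_lengths(mesh.points, mesh.edges)
    theta0 = _kernels.dihedral_angles(mesh.points, mesh.edges, mesh.edge_apex)
    if np.any(theta0 <= 0.0) or np.any(theta0 >= 2.0 * np.pi):
        bad_e = int(np.argmax((theta0 <= 0.0) | (theta0 >= 2.0 * np.pi)))
        raise MeshError(f"rest dihedral out of (0, 2π) at edge {bad_e}")
    vol = _kernels.signed_volume(mesh.points, mesh.faces)
    return RestState(
        edge_lengths=L0,
        dihedrals=theta0,
        triangle_areas=areas,
        area=float(areas.sum()),
        volume=float(vol),
    )


def geometry_queries(
    mesh: TriMesh, positions: np.ndarray, rest: RestState | None = None
) -> GeometryState:
    """All instantaneous geometric quantities for a configuration.

    Stretch ratios require a rest state; if none is given, the mesh's own
    reference shape is used.
    """
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    if pos.shape != mesh.points.shape:
        raise ValueError("positions not index-compatible with mesh")
    if rest is None:
        rest = compute_rest_state(mesh)
    areas, normals, centroids, tsq = _kernels.triangle_geometry(pos, mesh.faces)
    L = _kernels.edge_lengths(pos, mesh.edges)
    theta = _kernels.dihedral_angles(pos, mesh.edges, mesh.edge_apex)
    return GeometryState(
        stretches=L / rest.edge_lengths,
        dihedrals=theta,
        triangle_areas=areas,
        triangle_normals=normals,
        triangle_centroids=centroids,
        centroid_dist_sq=tsq,
        area=float(areas.sum()),
        volume=float(_kernels.signed_volume(pos, mesh.faces)),
        degenerate_triangles=areas <= 0.0,
    )


# ---------------------------------------------------------------------------
# text mesh format:  "nodes N triangles M" header, N xyz lines, M ijk lines
# ---------------------------------------------------------------------------


def save_mesh(mesh: TriMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"nodes {mesh.n_nodes} triangles {mesh.faces.shape[0]}\n")
        for x, y, z in mesh.points:
            fh.write(f"{x:.12g} {y:.12g} {z:.12g}\n")
        for a, b, c in mesh.faces:
            fh.write(f"{a} {b} {c}\n")


def load_mesh(path) -> TriMesh:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 4 or header[0] != "nodes" or header[2] != "triangles":
            raise MeshError(f"bad mesh header in {path}")
        n, m = int(header[1]), int(header[3])
        pts = np.array(
            [[float(v) for v in fh.readline().split()] for _ in range(n)]
        )
        faces = np.array(
            [[int(v) for v in fh.readline().split()] for _ in range(m)],
            dtype=np.int64,
        )
    return TriMesh(points=pts, faces=faces)
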
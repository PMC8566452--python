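"""Kelvin–Voigt membrane force laws on a spring-network cell.

The membrane is a triangulated network of parallel spring/dashpot elements
plus bending, local-area, global-area and global-volume constraints. Six
coefficients control it:

=========  =====================================================
k_s        neo-Hookean edge stretching modulus
k_b        dihedral bending modulus
k_al       local (per-triangle) area modulus
k_ag       global area modulus
k_V        global volume modulus
k_visc     edge dashpot (membrane viscosity) coefficient
=========  =====================================================

Internal unit system: lengths in µm, time in µs, mass in pg, hence forces
in nN. The moduli are treated as given in this system; configurable scale
factors can be applied by the caller if a different convention is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .mesh import RestState, TriMesh

__all__ = [
    "ElasticParams",
    "CellState",
    "kappa",
    "stretching_forces",
    "bending_forces",
    "area_volume_forces",
    "viscous_forces",
    "total_elastic_forces",
]

VISCOUS_MODES = ("literal", "relative")


@dataclass(frozen=True)
class ElasticParams:
    """The identifiable viscoelastic coefficients of the membrane model."""

    k_s: float
    k_b: float
    k_al: float
    k_ag: float
    k_V: float
    k_visc: float

    def __post_init__(self) -> None:
        for name in ("k_s", "k_b", "k_al", "k_ag", "k_V", "k_visc"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.k_s, self.k_b, self.k_al, self.k_ag, self.k_V, self.k_visc]
        )

    @classmethod
    def from_array(cls, a) -> "ElasticParams":
        return cls(*(float(v) for v in a))

    def scaled(self, factor: float) -> "ElasticParams":
        return ElasticParams.from_array(self.as_array() * factor)


@dataclass
class CellState:
    """Positions (µm), velocities (µm/µs) and per-node masses (pg)."""

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.masses = np.ascontiguousarray(self.masses, dtype=np.float64)
        n = self.positions.shape[0]
        if self.velocities.shape != (n, 3) or self.masses.shape != (n,):
            raise ValueError("state arrays have inconsistent lengths")
        if np.any(self.masses <= 0.0):
            raise ValueError("node masses must be positive")

    @classmethod
    def at_rest(cls, mesh: TriMesh, density: float = 1.05) -> "CellState":
        """Cell at its reference shape; total mass = density × volume,
        distributed uniformly (density in pg/µm³ = 10³ kg/m³)."""
        n = mesh.n_nodes
        m = density * mesh.volume() / n
        return cls(
            positions=mesh.points.copy(),
            velocities=np.zeros((n, 3)),
            masses=np.full(n, m),
        )


def kappa(lam):
    """Neo-Hookean stiffening factor (λ^0.5 + λ^−2.5)/(λ + λ^−3).

    Equals 1 at rest (λ = 1), falls below 1 in extension and rises above 1
    in compression.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("stretch ratio must be positive")
    out = (lam**0.5 + lam**-2.5) / (lam + lam**-3.0)
    return float(out) if out.ndim == 0 else out


def _check_positions(mesh: TriMesh, positions: np.ndarray) -> np.ndarray:
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    if pos.shape != mesh.points.shape:
        raise ValueError("positions not index-compatible with mesh")
    return pos


def stretching_forces(
    mesh: TriMesh, rest: RestState, positions: np.ndarray, k_s: float
) -> np.ndarray:
    """Per-node forces from the neo-Hookean edge springs."""
    pos = _check_positions(mesh, positions)
    L = _kernels.edge_lengths(pos, mesh.edges)
    if np.any(L == 0.0):
        raise ValueError(f"degenerate edge {int(np.argmin(L))} (zero length)")
    out = np.zeros_like(pos)
    _kernels.stretch_forces(pos, mesh.edges, rest.edge_lengths, k_s, out)
    return out


def bending_forces(
    mesh: TriMesh, rest: RestState, positions: np.ndarray, k_b: float
) -> np.ndarray:
    """Per-node forces restoring the rest dihedral angles.

    The pair load of magnitude k_b (θ−θ0)/θ0 acts on the apex vertices
    along their triangles' normals and is compensated on the two shared
    vertices so the pair's net force is exactly zero.
    """
    pos = _check_positions(mesh, positions)
    out = np.zeros_like(pos)
    _kernels.bending_forces(
        pos, mesh.edges, mesh.edge_apex, rest.dihedrals, k_b, out
    )
    return out


def area_volume_forces(
    mesh: TriMesh,
    rest: RestState,
    positions: np.ndarray,
    k_al: float,
    k_ag: float,
    k_V: float,
) -> np.ndarray:
    """Local-area, global-area and global-volume constraint forces."""
    pos = _check_positions(mesh, positions)
    areas, _, _, _ = _kernels.triangle_geometry(pos, mesh.faces)
    if np.any(areas <= 0.0):
        raise ValueError(f"degenerate triangle {int(np.argmin(areas))}")
    out = np.zeros_like(pos)
    _kernels.area_volume_forces(
        pos,
        mesh.faces,
        rest.triangle_areas,
        rest.area,
        rest.volume,
        k_al,
        k_ag,
        k_V,
        out,
    )
    return out


def viscous_forces(
    mesh: TriMesh,
    positions: np.ndarray,
    velocities: np.ndarray,
    k_visc: float,
    mode: str = "relative",
) -> np.ndarray:
    """Edge dashpot forces.

    ``literal`` projects each node's own velocity on its incident edges;
    ``relative`` (default) substitutes the edge-relative velocity
    v_A − v_B, which makes the damping Galilean invariant and momentum
    conserving.
    """
    if mode not in VISCOUS_MODES:
        raise ValueError(f"unknown viscous mode {mode!r}; use one of {VISCOUS_MODES}")
    pos = _check_positions(mesh, positions)
    vel = np.ascontiguousarray(velocities, dtype=np.float64)
    out = np.zeros_like(pos)
    _kernels.viscous_forces(pos, vel, mesh.edges, k_visc, mode == "relative", out)
    return out


def total_elastic_forces(
    mesh: TriMesh, rest: RestState, positions: np.ndarray, params: ElasticParams
) -> np.ndarray:
    """Sum of the five elastic force laws (no dashpot)."""
    pos = _check_positions(mesh, positions)
    out = np.zeros_like(pos)
    _kernels.stretch_forces(pos, mesh.edges, rest.edge_lengths, params.k_s, out)
    _kernels.bending_forces(
        pos, mesh.edges, mesh.edge_apex, rest.dihedrals, params.k_b, out
    )
    _kernels.area_volume_forces(
        pos,
        mesh.faces,
        rest.triangle_areas,
        rest.area,
        rest.volume,
        params.k_al,
        params.k_ag,
        params.k_V,
        out,
    )
    return out
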
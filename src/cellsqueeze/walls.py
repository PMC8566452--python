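"""Node–wall repulsion and sliding friction.

Two short-range forces act on membrane nodes within a threshold distance
d_cut of a channel wall:

* a repulsive force a·n/d^(n+1) along the wall normal, which keeps nodes
  from penetrating the solid, and
* a kinetic friction force of magnitude μ_f times the repulsive magnitude,
  directed against the node's velocity.

The friction is purely kinetic: below a small velocity dead-band ε_v it is
zero (no static friction model). By default it opposes the full nodal
velocity as printed; a ``tangential`` option projects out the wall-normal
component, the physically common alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channel import ChannelGeometry

__all__ = [
    "WallInteractionParams",
    "repulsive_force",
    "friction_force",
    "nearest_wall_distance",
    "wall_node_forces",
]


@dataclass(frozen=True)
class WallInteractionParams:
    """Repulsion/friction parameters (force scale a gives nN at d in µm)."""

    a: float = 0.0001
    n_exp: float = 1.2
    d_cut: float = 0.1  # µm
    mu_f: float = 0.0
    d_min: float = 1e-3  # clamp for penetrating nodes, µm
    eps_v: float = 1e-6  # friction velocity dead-band, µm/µs
    tangential: bool = False

    def __post_init__(self) -> None:
        if self.a < 0 or self.n_exp <= 0 or self.d_cut <= 0 or self.mu_f < 0:
            raise ValueError("invalid wall-interaction parameters")


def _repulsive_magnitude(d: float, params: WallInteractionParams) -> float:
    return params.a * params.n_exp / d ** (params.n_exp + 1.0)


def repulsive_force(
    d: float, m_hat, params: WallInteractionParams
) -> np.ndarray:
    """Wall repulsion on a node at distance d, along the unit wall→node
    direction ``m_hat``; zero at or beyond d_cut (strict inequality)."""
    m_hat = np.asarray(m_hat, dtype=float)
    if d <= 0.0:
        d = params.d_min  # penetration: clamp; callers log the event
    if d >= params.d_cut:
        return np.zeros(3)
    return _repulsive_magnitude(d, params) * m_hat


def friction_force(
    v_node, d: float, params: WallInteractionParams, m_hat=None
) -> np.ndarray:
    """Kinetic friction: μ_f × repulsive magnitude, opposing the velocity.

    With ``params.tangential`` the wall-normal velocity component is
    removed first (requires ``m_hat``).
    """
    v = np.asarray(v_node, dtype=float)
    if d <= 0.0:
        d = params.d_min
    if d >= params.d_cut or params.mu_f == 0.0:
        return np.zeros(3)
    if params.tangential:
        if m_hat is None:
            raise ValueError("tangential friction needs the wall normal")
        m = np.asarray(m_hat, dtype=float)
        v = v - np.dot(v, m) * m
    speed = np.linalg.norm(v)
    if speed <= params.eps_v:
        return np.zeros(3)
    return -params.mu_f * _repulsive_magnitude(d, params) * v / speed


def nearest_wall_distance(
    position, geometry: ChannelGeometry
) -> tuple[float, np.ndarray]:
    """Distance to the nearest channel wall and the wall→fluid direction.

    Negative distance means the point is inside the solid (penetration).
    """
    return geometry.wall_distance(position)


def wall_node_forces(
    positions: np.ndarray,
    velocities: np.ndarray,
    geometry: ChannelGeometry,
    params: WallInteractionParams,
) -> tuple[np.ndarray, int]:
    """Repulsion + friction accumulated over all nodes.

    Returns (forces, penetration_count); penetrations are evaluated at the
    clamped distance d_min.
    """
    from . import _kernels

    pos = np.ascontiguousarray(positions, dtype=np.float64)
    vel = np.ascontiguousarray(velocities, dtype=np.float64)
    out = np.zeros_like(pos)
    npen = _kernels.wall_forces(
        pos,
        vel,
        geometry.side_segments(),
        geometry.depth,
        params.a,
        params.n_exp,
        params.d_cut,
        params.mu_f,
        params.d_min,
        params.eps_v,
        out,
    )
    return out, int(npen)
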
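"""Dissipative fluid–membrane coupling.

Each membrane node feels a drag force F = ξ(u − v) toward the local fluid
velocity u (trilinearly interpolated), and the opposite impulse is
deposited back onto the fluid through the same trilinear stencil, so the
exchange conserves momentum exactly. ξ is a phenomenological friction
coefficient calibrated for a reference sphere (radius 4 µm, 393 nodes) and
rescaled to other objects by node count and surface area.

ξ is in nN·s/m, which in the internal µm/µs/pg unit system is numerically
identical to nN·µs/µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .lbm import FluidLattice

__all__ = [
    "XI_REF_TABLE",
    "CouplingParams",
    "xi_ref_for_viscosity",
    "xi_for_object",
    "interpolate_velocity",
    "drag_and_backforce",
]

#: Calibrated reference friction (dynamic viscosity mPa·s → ξ_ref nN·s/m)
#: for the reference sphere r = 4 µm, n = 393.
XI_REF_TABLE = ((1.0, 1.18), (1.3, 1.54), (1.5375, 1.82))

N_REF = 393
R_REF = 4.0  # µm
S_REF = 4.0 * np.pi * R_REF**2  # µm²


def xi_ref_for_viscosity(viscosity_mPas: float) -> float:
    """Reference friction coefficient for a fluid of given dynamic viscosity.

    Piecewise-linear interpolation on the calibrated table, extrapolating
    from the two nearest tabulated points outside its range (e.g. 0.785
    mPa·s → 0.922 nN·s/m).
    """
    if viscosity_mPas <= 0:
        raise ValueError("viscosity must be positive")
    if not 0.5 <= viscosity_mPas <= 2.5:
        import warnings

        warnings.warn(
            f"viscosity {viscosity_mPas} mPa·s far outside the calibrated "
            "range; extrapolating", stacklevel=2,
        )
    pts = sorted(XI_REF_TABLE)
    # two nearest tabulated points by |υ − υ_i|
    (x0, y0), (x1, y1) = sorted(pts, key=lambda p: abs(p[0] - viscosity_mPas))[:2]
    return y0 + (y1 - y0) * (viscosity_mPas - x0) / (x1 - x0)


def xi_for_object(n_nodes: int, surface_area: float, xi_ref: float) -> float:
    """Rescale ξ_ref to an object with n nodes and surface area S (µm²):
    ξ = (n_ref/n)·√(S/S_ref)·ξ_ref."""
    if n_nodes <= 0 or surface_area <= 0:
        raise ValueError("node count and surface area must be positive")
    return (N_REF / n_nodes) * np.sqrt(surface_area / S_REF) * xi_ref


@dataclass(frozen=True)
class CouplingParams:
    """Friction coefficient of the dissipative membrane–fluid coupling."""

    xi: float  # nN·s/m (≡ nN·µs/µm)
    literal_sign: bool = False  # printed-form F = ξ(v−u); comparison only

    def __post_init__(self) -> None:
        if self.xi <= 0:
            raise ValueError("ξ must be positive")

    @classmethod
    def for_cell(
        cls, n_nodes: int, surface_area: float, viscosity_mPas: float | None = None,
        xi_ref: float | None = None,
    ) -> "CouplingParams":
        if xi_ref is None:
            if viscosity_mPas is None:
                raise ValueError("give either viscosity or xi_ref")
            xi_ref = xi_ref_for_viscosity(viscosity_mPas)
        return cls(xi=xi_for_object(n_nodes, surface_area, xi_ref))


def _to_lattice_coords(lattice: FluidLattice, positions: np.ndarray, origin: np.ndarray):
    """Physical positions (µm) → lattice coordinates (site centers at
    integers), given the physical position of site (0,0,0)."""
    return (np.asarray(positions) - origin) / lattice.units.dx


def interpolate_velocity(
    lattice: FluidLattice,
    positions: np.ndarray,
    origin: np.ndarray | None = None,
    u_field: np.ndarray | None = None,
) -> np.ndarray:
    """Fluid velocity (µm/µs) at physical positions, trilinear from the 8
    surrounding sites. Solid stencil sites contribute zero velocity; a
    query whose nearest site is solid is served from the remaining fluid
    sites (and counted — callers may log it)."""
    if origin is None:
        origin = np.zeros(3)
    if u_field is None:
        _, u_field = lattice.moments()
    p = np.ascontiguousarray(_to_lattice_coords(lattice, positions, origin))
    out = np.empty((p.shape[0], 3))
    _kernels.interpolate_velocity_kernel(
        u_field, lattice.solid,
        np.ascontiguousarray(p[:, 0]),
        np.ascontiguousarray(p[:, 1]),
        np.ascontiguousarray(p[:, 2]),
        out,
    )
    return lattice.units.velocity_from_lattice(out)


def drag_and_backforce(
    lattice: FluidLattice,
    positions: np.ndarray,
    velocities: np.ndarray,
    params: CouplingParams,
    origin: np.ndarray | None = None,
    deposit: bool = True,
    u_field: np.ndarray | None = None,
) -> np.ndarray:
    """Drag forces on the nodes (nN); equal-and-opposite momentum deposited
    onto the fluid's transient force field when ``deposit``.

    The deposit is the force itself (the lattice applies it over one fluid
    step), spread with the same trilinear weights used for interpolation.
    """
    if origin is None:
        origin = np.zeros(3)
    u = interpolate_velocity(lattice, positions, origin, u_field=u_field)
    sign = -1.0 if params.literal_sign else 1.0
    forces = sign * params.xi * (u - np.asarray(velocities))
    if deposit:
        p = _to_lattice_coords(lattice, positions, origin)
        lattice.deposit_forces(p, lattice.units.force_to_lattice(-forces))
    return forces
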
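"""Experiment drivers: cell passage through a constriction, and axial
stretching between two polar contact caps (the optical-tweezers setup).

The membrane nodes follow Newton's second law, m_j ẍ = F_j, integrated
with velocity Verlet for the position-dependent forces. The stiff
velocity-dependent terms — edge dashpots, wall friction and fluid drag —
are applied after the Verlet update as momentum-conserving impulse
updates (pairwise-implicit dashpot, velocity-clipped friction, exact
exponential drag relaxation), which keeps the scheme stable at time steps
where a fully explicit treatment of those terms would blow up. The fluid
may be subcycled: one lattice step per ``fluid_substeps`` membrane steps,
with the accumulated drag back-reaction deposited each fluid step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .channel import ChannelGeometry
from .coupling import CouplingParams, interpolate_velocity
from .forces import CellState, ElasticParams, total_elastic_forces
from .lbm import FluidLattice, UnitMap, calibrate_driving, kinematic_viscosity
from .mesh import RestState, TriMesh, compute_rest_state
from .metrics import detect_entry_transit, observables
from .walls import WallInteractionParams

__all__ = [
    "Numerics",
    "PassageResult",
    "StretchResult",
    "integrate_step",
    "run_channel_passage",
    "run_stretch",
]


@dataclass(frozen=True)
class Numerics:
    """Discretization and run-control settings for a passage simulation."""

    dt: float = 0.01  # membrane time step, µs
    dx: float = 1.0  # lattice spacing, µm
    fluid_substeps: int = 1  # membrane steps per fluid step
    sample_every: int = 25  # metric sampling interval, membrane steps
    max_steps: int = 2_000_000
    release_standoff: float = 0.2  # gap between leading edge and taper plane, µm
    exit_margin: float = 0.5  # stop once trailing edge clears exit + margin, µm
    stall_horizon: float = 50.0  # µs without trailing-edge progress → stalled
    stall_tol: float = 1e-3  # µm of progress that counts
    viscosity_mPas: float = 0.785
    rho_f_kg_m3: float = 1006.0
    rho_cell_kg_m3: float = 1050.0

    @property
    def fluid_dt(self) -> float:
        return self.dt * self.fluid_substeps


@dataclass
class PassageResult:
    entry_time: float | None  # µs
    transit_time: float | None  # µs
    stalled: bool
    completed: bool
    times: np.ndarray  # µs
    length: np.ndarray
    area_strain: np.ndarray
    leading_x: np.ndarray
    trailing_x: np.ndarray
    centroid_x: np.ndarray
    mean_speed: np.ndarray  # µm/µs
    penetration_events: int
    flow_rate_uL_h: float
    volume_min: float = float("nan")  # extreme cell volumes seen, µm³
    volume_max: float = float("nan")

    @property
    def passage_time(self) -> float | None:
        if self.entry_time is None or self.transit_time is None:
            return None
        return self.entry_time + self.transit_time


@dataclass
class StretchResult:
    forces: np.ndarray  # applied load per point, nN
    axial_diameter: np.ndarray  # µm
    transverse_diameter: np.ndarray  # µm
    residuals: np.ndarray  # final force residual per point, nN


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------


def integrate_step(state: CellState, force_fn, dt: float, f_prev=None):
    """One velocity-Verlet step of m ẍ = F(x).

    ``force_fn(positions) -> (N, 3)``; pass the returned forces back in as
    ``f_prev`` on the next call to avoid re-evaluating them. Returns the
    forces at the new positions.
    """
    m = state.masses[:, None]
    if f_prev is None:
        f_prev = force_fn(state.positions)
    vh = state.velocities + 0.5 * dt * f_prev / m
    state.positions = state.positions + dt * vh
    f_new = force_fn(state.positions)
    state.velocities = vh + 0.5 * dt * f_new / m
    return f_new


def _drag_impulses(vel, masses, u_fluid, xi, dt):
    """Exact relaxation of node velocities toward the fluid velocity.

    Returns the per-node impulses delivered to the nodes (the fluid gets
    the exact opposite).
    """
    alpha = 1.0 - np.exp(-xi * dt / masses)
    dv = (u_fluid - vel) * alpha[:, None]
    vel += dv
    return dv * masses[:, None]


# ---------------------------------------------------------------------------
# channel passage
# ---------------------------------------------------------------------------


def _check_finite(arr, step):
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError(f"non-finite membrane state at step {step}")


def run_channel_passage(
    mesh: TriMesh,
    params: ElasticParams,
    mu_f: float,
    flow_rate_uL_h: float,
    geometry: ChannelGeometry,
    numerics: Numerics = Numerics(),
    wall: WallInteractionParams | None = None,
    rest: RestState | None = None,
    xi: float | None = None,
    prepared_fluid: tuple[np.ndarray, np.ndarray] | None = None,
) -> PassageResult:
    """Simulate one cell passing the constriction at a given flow rate.

    The blank channel is calibrated to the target flow rate and converged
    to steady state before the cell is released just upstream of the taper
    entrance; ``prepared_fluid`` (body force, populations) can short-cut
    that for repeated runs. The entry clock starts when the leading edge
    crosses the taper-entrance plane, entry completes when the trailing
    edge crosses the constriction-entrance plane, and transit ends when the
    trailing edge clears the constriction exit.
    """
    from .coupling import xi_ref_for_viscosity, xi_for_object

    if wall is None:
        wall = WallInteractionParams()
    wall = replace(wall, mu_f=mu_f)
    if rest is None:
        rest = compute_rest_state(mesh)

    nu = kinematic_viscosity(numerics.viscosity_mPas, numerics.rho_f_kg_m3)
    units = UnitMap(
        dx=numerics.dx, dt=numerics.fluid_dt, rho_f=numerics.rho_f_kg_m3 * 1e-3
    )
    tau = units.tau_for_viscosity(nu)
    solid = geometry.solid_mask(numerics.dx)
    origin = geometry.lattice_origin(numerics.dx)

    if prepared_fluid is None:
        body_force, blank = calibrate_driving(solid, units, tau, flow_rate_uL_h)
        f0 = blank.f
    else:
        body_force, f0 = prepared_fluid
    lattice = FluidLattice(solid=solid, tau=tau, units=units, body_force=body_force)
    lattice.f[:] = f0

    if xi is None:
        xi_ref = xi_ref_for_viscosity(numerics.viscosity_mPas)
        xi = xi_for_object(mesh.n_nodes, rest.area, xi_ref)

    # place the cell on the axis, leading edge just upstream of the taper
    state = CellState.at_rest(mesh, density=numerics.rho_cell_kg_m3 * 1e-3)
    target_lead = geometry.taper_entrance_x - numerics.release_standoff
    shift = np.array(
        [
            target_lead - state.positions[:, 0].max(),
            -state.positions[:, 1].mean(),
            0.5 * geometry.depth - state.positions[:, 2].mean(),
        ]
    )
    state.positions = state.positions + shift
    dmin = min(geometry.wall_distance(p)[0] for p in state.positions)
    if dmin < wall.d_cut:
        raise ValueError(
            f"cell does not fit the channel with clearance d_cut "
            f"(closest wall {dmin:.3f} µm)"
        )

    seg = geometry.side_segments()
    dt = numerics.dt
    K = numerics.fluid_substeps
    exit_plane = geometry.constriction_exit_x
    vel_scale = units.dx / units.dt  # lattice → µm/µs

    times, lengths, strains, leads, trails, cents, speeds = ([] for _ in range(7))
    penetrations = 0
    vol_min, vol_max = np.inf, -np.inf
    _, u_field = lattice.moments()
    imp_grid = np.zeros((3,) + lattice.shape)

    pos = state.positions
    vel = state.velocities
    f_prev = np.zeros_like(pos)
    penetrations += _kernels.elastic_and_wall_forces(
        pos, vel, mesh.edges, mesh.edge_apex, mesh.faces,
        rest.edge_lengths, rest.dihedrals, rest.triangle_areas,
        rest.area, rest.volume,
        params.k_s, params.k_b, params.k_al, params.k_ag, params.k_V,
        seg, geometry.depth, wall.a, wall.n_exp, wall.d_cut, wall.d_min,
        wall.eps_v, f_prev,
    )
    stall_ref_trail = pos[:, 0].min()
    stall_ref_time = 0.0
    stalled = False
    completed = False

    if numerics.sample_every % K != 0:
        raise ValueError("sample_every must be a multiple of fluid_substeps")

    step = 0
    while step < numerics.max_steps:
        if step % numerics.sample_every == 0:
            obs = observables(mesh, rest, pos)
            times.append(step * dt)
            lengths.append(obs.length)
            strains.append(obs.area_strain)
            leads.append(obs.leading_x)
            trails.append(obs.trailing_x)
            cents.append(obs.centroid[0])
            speeds.append(float(np.linalg.norm(vel.mean(axis=0))))
            vol_min = min(vol_min, obs.volume)
            vol_max = max(vol_max, obs.volume)
            trail = obs.trailing_x
            t_now = step * dt
            if trail >= exit_plane + numerics.exit_margin:
                completed = True
                break
            if trail > stall_ref_trail + numerics.stall_tol:
                stall_ref_trail = trail
                stall_ref_time = t_now
            elif t_now - stall_ref_time >= numerics.stall_horizon:
                stalled = True
                break
            _check_finite(pos, step)

        penetrations += _kernels.membrane_substeps(
            pos, vel, state.masses, f_prev, K, dt,
            mesh.edges, mesh.edge_apex, mesh.faces,
            rest.edge_lengths, rest.dihedrals, rest.triangle_areas,
            rest.area, rest.volume,
            params.k_s, params.k_b, params.k_al, params.k_ag, params.k_V,
            params.k_visc,
            seg, geometry.depth, wall.a, wall.n_exp, wall.d_cut, mu_f,
            wall.d_min, wall.eps_v,
            u_field, lattice.solid, origin[0], origin[1], origin[2],
            units.dx, vel_scale, xi, imp_grid,
        )
        step += K
        # apply the accumulated back-reaction and advance the fluid
        lattice.extra_force += units.force_to_lattice(imp_grid / units.dt)
        imp_grid[:] = 0.0
        lattice.step(1)
        _, u_field = lattice.moments()

    _check_finite(pos, step)
    times_a = np.asarray(times)
    leads_a = np.asarray(leads)
    trails_a = np.asarray(trails)
    entry, transit = detect_entry_transit(
        times_a, leads_a, trails_a,
        geometry.taper_entrance_x,
        geometry.constriction_entrance_x,
        geometry.constriction_exit_x,
    )
    return PassageResult(
        entry_time=entry,
        transit_time=transit,
        stalled=stalled,
        completed=completed,
        times=times_a,
        length=np.asarray(lengths),
        area_strain=np.asarray(strains),
        leading_x=leads_a,
        trailing_x=trails_a,
        centroid_x=np.asarray(cents),
        mean_speed=np.asarray(speeds),
        penetration_events=penetrations,
        flow_rate_uL_h=flow_rate_uL_h,
        volume_min=float(vol_min),
        volume_max=float(vol_max),
    )


# ---------------------------------------------------------------------------
# axial stretch (optical-tweezers protocol)
# ---------------------------------------------------------------------------


def run_stretch(
    mesh: TriMesh,
    params: ElasticParams,
    force_list,
    contact_fraction: float = 0.1,
    rest: RestState | None = None,
    dt: float = 0.1,
    damping: float = 1.0,
    residual_tol: float = 1e-4,
    max_steps_per_force: int = 60_000,
) -> StretchResult:
    """Quasi-static axial stretch: ±F/N_c on the two polar contact caps.

    The caps are the nodes within ``contact_fraction`` of the axial extent
    from each end (mimicking the bead contact patches). Each load is
    relaxed to equilibrium by damped dynamics, warm-starting from the
    previous load; the axial and transverse diameters are read from
    extremal node coordinates.
    """
    if contact_fraction <= 0.0 or contact_fraction >= 0.5:
        raise ValueError("contact_fraction must lie in (0, 0.5)")
    forces = np.atleast_1d(np.asarray(force_list, dtype=float))
    if forces.size < 1:
        raise ValueError("need at least one load")
    if rest is None:
        rest = compute_rest_state(mesh)

    x = mesh.points[:, 0]
    extent = x.max() - x.min()
    cap_hi = np.where(x >= x.max() - contact_fraction * extent)[0]
    cap_lo = np.where(x <= x.min() + contact_fraction * extent)[0]

    state = CellState.at_rest(mesh)
    m = state.masses[:, None]
    ax, tr, res = [], [], []
    for F in forces:
        applied = np.zeros_like(state.positions)
        applied[cap_hi, 0] = F / cap_hi.size
        applied[cap_lo, 0] = -F / cap_lo.size

        f_prev = total_elastic_forces(mesh, rest, state.positions, params) + applied
        residual = np.abs(f_prev).max()
        converged = residual < residual_tol
        for step in range(0 if converged else max_steps_per_force):
            vh = state.velocities + 0.5 * dt * f_prev / m
            state.positions = state.positions + dt * vh
            f_new = (
                total_elastic_forces(mesh, rest, state.positions, params) + applied
            )
            state.velocities = vh + 0.5 * dt * f_new / m
            f_prev = f_new
            # heavy viscous relaxation toward quasi-statics
            state.velocities *= math.exp(-damping * dt)
            if params.k_visc > 0.0:
                _kernels.pairwise_damping_impulses(
                    state.positions, state.velocities, mesh.edges,
                    params.k_visc, state.masses, dt,
                )
            if step % 200 == 199:
                residual = np.abs(f_new).max()
                vmax = np.abs(state.velocities).max()
                if residual < residual_tol and vmax < residual_tol:
                    converged = True
                    break
                if not np.all(np.isfinite(state.positions)):
                    raise FloatingPointError(
                        f"stretch relaxation diverged at load {F} nN"
                    )
        if not converged and residual >= residual_tol * 10:
            raise RuntimeError(
                f"stretch relaxation not converged at load {F} nN "
                f"(residual {residual:.3g} nN)"
            )
        p = state.positions
        ax.append(p[:, 0].max() - p[:, 0].min())
        d_y = p[:, 1].max() - p[:, 1].min()
        d_z = p[:, 2].max() - p[:, 2].min()
        tr.append(0.5 * (d_y + d_z))
        res.append(residual)
        state.velocities[:] = 0.0
    return StretchResult(
        forces=forces,
        axial_diameter=np.asarray(ax),
        transverse_diameter=np.asarray(tr),
        residuals=np.asarray(res),
    )
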
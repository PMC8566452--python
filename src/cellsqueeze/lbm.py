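"""D3Q19 lattice-Boltzmann fluid solver.

Single-relaxation-time (BGK) collisions with a standard second-order
equilibrium, Guo forcing with the half-force moment correction, and
half-way bounce-back walls on a voxelized channel mask. The domain is
periodic; flow is driven by a constant body force calibrated so the
blank-channel flow rate matches a target, mimicking a constant pressure
drop between the channel ends.

Physical units: µm, µs, pg (so forces in nN and pressure-like quantities
in nN/µm²); lattice units have δx = δt = 1 and c_s² = 1/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = [
    "D3Q19",
    "UnitMap",
    "FluidLattice",
    "equilibrium",
    "poiseuille_flow_rate",
    "calibrate_driving",
]

MAX_LATTICE_SPEED = 0.3  # |u| above this (lattice units) triggers a warning


def _build_d3q19():
    e = [(0, 0, 0)]
    e += [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    e += [
        (1, 1, 0), (-1, -1, 0), (1, -1, 0), (-1, 1, 0),
        (1, 0, 1), (-1, 0, -1), (1, 0, -1), (-1, 0, 1),
        (0, 1, 1), (0, -1, -1), (0, 1, -1), (0, -1, 1),
    ]
    e = np.array(e, dtype=np.int64)
    w = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12)
    opp = np.array([int(np.where((e == -v).all(axis=1))[0][0]) for v in e])
    return e, w, opp


class D3Q19:
    """The 19-velocity cubic lattice: vectors e_i, weights w_i, opposites."""

    E, W, OPP = _build_d3q19()
    EX = np.ascontiguousarray(E[:, 0], dtype=np.float64)
    EY = np.ascontiguousarray(E[:, 1], dtype=np.float64)
    EZ = np.ascontiguousarray(E[:, 2], dtype=np.float64)
    CS2 = 1.0 / 3.0


@dataclass(frozen=True)
class UnitMap:
    """Physical (µm, µs, pg) ↔ lattice unit conversion.

    The mass scale is fixed by mapping the physical fluid density to
    lattice density 1, i.e. one lattice mass unit is ρ_f δx³ picograms.
    """

    dx: float = 1.0  # µm per lattice spacing
    dt: float = 0.01  # µs per lattice step
    rho_f: float = 1.006  # fluid density, pg/µm³ (= 10³ kg/m³)

    @property
    def mass_unit(self) -> float:
        """pg per lattice mass unit."""
        return self.rho_f * self.dx**3

    # velocities -----------------------------------------------------------
    def velocity_to_lattice(self, v):
        return np.asarray(v) * self.dt / self.dx

    def velocity_from_lattice(self, v):
        return np.asarray(v) * self.dx / self.dt

    # kinematic viscosity ---------------------------------------------------
    def viscosity_to_lattice(self, nu_phys: float) -> float:
        """µm²/µs → lattice; τ follows from ν = c_s²(τ − ½)."""
        return nu_phys * self.dt / self.dx**2

    def tau_for_viscosity(self, nu_phys: float) -> float:
        return self.viscosity_to_lattice(nu_phys) / D3Q19.CS2 + 0.5

    # forces ----------------------------------------------------------------
    def force_to_lattice(self, f):
        """nN → lattice force (per-site body force from a point force)."""
        return np.asarray(f) * self.dt**2 / (self.dx * self.mass_unit)

    def force_from_lattice(self, f):
        return np.asarray(f) * self.dx * self.mass_unit / self.dt**2

    # flow rate -------------------------------------------------------------
    def flow_rate_to_lattice(self, q_um3_per_us: float) -> float:
        return q_um3_per_us * self.dt / self.dx**3

    def flow_rate_from_lattice(self, q_lat: float) -> float:
        return q_lat * self.dx**3 / self.dt


def kinematic_viscosity(dynamic_viscosity_mPas: float, density_kg_m3: float) -> float:
    """Dynamic viscosity (mPa·s) and density (kg/m³) → ν in µm²/µs."""
    return dynamic_viscosity_mPas * 1e-3 / density_kg_m3 * 1e6


def poiseuille_flow_rate(
    pressure_psi: float,
    reference_flow_uL_h: float = 38.0,
    reference_pressure_psi: float = 1.5,
) -> float:
    """Flow rate at a driving pressure by linear (Poiseuille) scaling.

    In the Stokes regime the volumetric rate through a fixed channel is
    proportional to the applied pressure drop, so a single blank-medium
    reference measurement fixes the whole line.
    """
    if reference_pressure_psi <= 0:
        raise ValueError("reference pressure must be positive")
    return reference_flow_uL_h * pressure_psi / reference_pressure_psi


UL_PER_H_TO_UM3_PER_US = 1e9 / 3.6e9  # 1 µL/h in µm³/µs


def equilibrium(rho, u):
    """Second-order LBGK equilibrium populations for (ρ, u) fields.

    ``rho``: (...,) array; ``u``: (..., 3) array (lattice units). Returns
    populations with shape (19, ...).
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("density must be positive")
    speed = np.sqrt((u**2).sum(axis=-1))
    if np.any(speed > MAX_LATTICE_SPEED):
        import warnings

        warnings.warn(
            f"lattice speed {speed.max():.3f} exceeds stability bound "
            f"{MAX_LATTICE_SPEED}", stacklevel=2,
        )
    eu = np.tensordot(D3Q19.E.astype(float), np.moveaxis(u, -1, 0), axes=(1, 0))
    usq = (u**2).sum(axis=-1)
    w = D3Q19.W.reshape((19,) + (1,) * rho.ndim)
    return w * rho * (1.0 + 3.0 * eu + 4.5 * eu**2 - 1.5 * usq)


@dataclass
class FluidLattice:
    """Populations + walls + forcing on a D3Q19 lattice.

    ``solid`` marks wall sites; ``body_force`` is the constant driving
    (lattice units, applied to every fluid site); ``extra_force`` holds
    transient per-site deposits (e.g. cell back-reaction) and is cleared
    after every step.
    """

    solid: np.ndarray
    tau: float
    units: UnitMap = field(default_factory=UnitMap)
    body_force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    f: np.ndarray = field(init=False)
    extra_force: np.ndarray = field(init=False)
    _fpost: np.ndarray = field(init=False, repr=False)
    _fnew: np.ndarray = field(init=False, repr=False)
    step_count: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if self.tau <= 0.5:
            raise ValueError(f"relaxation time τ = {self.tau} must exceed 0.5")
        self.solid = np.ascontiguousarray(self.solid, dtype=np.bool_)
        shape = (19,) + self.solid.shape
        self.f = np.empty(shape)
        rho0 = np.ones(self.solid.shape)
        self.f[:] = equilibrium(rho0, np.zeros(self.solid.shape + (3,)))
        self._fpost = np.empty_like(self.f)
        self._fnew = np.empty_like(self.f)
        self.extra_force = np.zeros((3,) + self.solid.shape)
        self.body_force = np.asarray(self.body_force, dtype=float)

    # -- helpers ------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.solid.shape

    def _force_field(self) -> np.ndarray:
        field_ = self.extra_force.copy()
        fluid = ~self.solid
        for k in range(3):
            field_[k][fluid] += self.body_force[k]
            field_[k][self.solid] = 0.0
        return field_

    def moments(self) -> tuple[np.ndarray, np.ndarray]:
        """(ρ, u) fields in lattice units, with the half-force correction."""
        rho, u = _kernels.lbm_moments(
            self.f, self.solid, self._force_field(),
            D3Q19.EX, D3Q19.EY, D3Q19.EZ,
        )
        return rho, u

    def mass(self) -> float:
        return float(self.f[:, ~self.solid].sum())

    def momentum(self) -> np.ndarray:
        """Total fluid momentum (lattice units), incl. the half-force shift."""
        ff = self._force_field()
        fluid = ~self.solid
        mom = np.array(
            [
                (self.f[:, fluid] * D3Q19.E[:, k, None]).sum()
                + 0.5 * ff[k][fluid].sum()
                for k in range(3)
            ]
        )
        return mom

    # -- dynamics -----------------------------------------------------------
    def step(self, n: int = 1) -> None:
        ff = self._force_field()
        for _ in range(n):
            _kernels.lbm_collide_stream(
                self.f, self._fpost, self._fnew, self.solid, self.tau, ff,
                D3Q19.EX, D3Q19.EY, D3Q19.EZ, D3Q19.W, D3Q19.OPP,
            )
            self.f, self._fnew = self._fnew, self.f
            self.step_count += 1
        if np.any(self.f[:, ~self.solid] < -1e-12):
            i = np.argwhere(self.f.min(axis=0) < -1e-12)[0]
            raise FloatingPointError(
                f"negative population at site {tuple(i)} after step "
                f"{self.step_count}: lattice unstable"
            )
        self.extra_force[:] = 0.0

    def deposit_forces(self, positions_lat: np.ndarray, forces_lat: np.ndarray) -> None:
        """Spread point forces (lattice units, positions in lattice coords)
        onto ``extra_force`` with the trilinear stencil."""
        _kernels.deposit_forces_kernel(
            self.extra_force, self.solid,
            np.ascontiguousarray(positions_lat[:, 0]),
            np.ascontiguousarray(positions_lat[:, 1]),
            np.ascontiguousarray(positions_lat[:, 2]),
            np.ascontiguousarray(forces_lat[:, 0]),
            np.ascontiguousarray(forces_lat[:, 1]),
            np.ascontiguousarray(forces_lat[:, 2]),
        )

    def flow_rate(self, ix: int | None = None) -> float:
        """Volumetric flow through the y–z plane at slab ix (µm³/µs)."""
        _, u = self.moments()
        if ix is None:
            ix = self.shape[0] // 2
        fluid = ~self.solid[ix]
        q_lat = u[0, ix][fluid].sum()  # Σ u_x · (δx_lat²=1)
        return self.units.flow_rate_from_lattice(q_lat)

    def run_to_steady(
        self,
        check_every: int = 50,
        rtol: float = 1e-5,
        max_steps: int = 200_000,
        probe_ix: int | None = None,
    ) -> float:
        """Step until the probe-plane flow rate stops changing; return it."""
        prev = None
        for _ in range(0, max_steps, check_every):
            self.step(check_every)
            q = self.flow_rate(probe_ix)
            if prev is not None and abs(q - prev) <= rtol * max(abs(q), 1e-300):
                return q
            prev = q
        raise RuntimeError(
            f"flow did not reach steady state in {max_steps} steps "
            f"(last Q = {prev})"
        )


def calibrate_driving(
    solid: np.ndarray,
    units: UnitMap,
    tau: float,
    target_flow_uL_h: float,
    probe_ix: int | None = None,
    rtol: float = 0.01,
    max_iter: int = 6,
    steady_rtol: float = 1e-5,
) -> tuple[np.ndarray, "FluidLattice"]:
    """Body force (lattice units, +x) reproducing a blank-channel flow rate.

    Exploits Stokes linearity: run a trial force to steady state, rescale
    by target/measured, repeat until within ``rtol``. Returns the force
    vector and the converged blank lattice (reusable as the pre-converged
    initial flow of a passage run).
    """
    if target_flow_uL_h < 0:
        raise ValueError("flow rate must be non-negative")
    lat = FluidLattice(solid=solid, tau=tau, units=units)
    if target_flow_uL_h == 0.0:
        return np.zeros(3), lat
    q_target = target_flow_uL_h * UL_PER_H_TO_UM3_PER_US
    g = 1e-6
    last_q = None
    for _ in range(max_iter):
        lat.body_force = np.array([g, 0.0, 0.0])
        q = lat.run_to_steady(rtol=steady_rtol, probe_ix=probe_ix)
        last_q = q
        if abs(q - q_target) <= rtol * q_target:
            return lat.body_force.copy(), lat
        g *= q_target / q
    raise RuntimeError(
        f"driving-force calibration did not converge: last Q = {last_q}, "
        f"target {q_target}"
    )
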
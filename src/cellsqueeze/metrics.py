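"""Scalar observables of a deforming cell and event detection.

Cell length is the axial (x) extent over nodes, the leading/trailing edges
are the extremal node x-coordinates, and the area strain is the relative
change of total membrane area from the undeformed shape, (S − S0)/S0. No
smoothing or averaging is applied anywhere. Entry and transit times are
linear-interpolated plane-crossing times of the edge traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .mesh import RestState, TriMesh

__all__ = [
    "CellObservables",
    "observables",
    "buoyant_mass",
    "radius_from_buoyant_mass",
    "first_crossing",
    "detect_entry_transit",
]


@dataclass(frozen=True)
class CellObservables:
    length: float  # µm, axial extent
    area_strain: float  # (S − S0)/S0
    leading_x: float  # µm
    trailing_x: float  # µm
    centroid: np.ndarray  # µm
    area: float  # µm²
    volume: float  # µm³


def observables(mesh: TriMesh, rest: RestState, positions: np.ndarray) -> CellObservables:
    pos = np.asarray(positions, dtype=float)
    areas, _, _, _ = _kernels.triangle_geometry(
        np.ascontiguousarray(pos), mesh.faces
    )
    S = float(areas.sum())
    lead = float(pos[:, 0].max())
    trail = float(pos[:, 0].min())
    return CellObservables(
        length=lead - trail,
        area_strain=(S - rest.area) / rest.area,
        leading_x=lead,
        trailing_x=trail,
        centroid=pos.mean(axis=0),
        area=S,
        volume=float(_kernels.signed_volume(np.ascontiguousarray(pos), mesh.faces)),
    )


def buoyant_mass(radius_um: float, rho_kg_m3: float, rho_f_kg_m3: float) -> float:
    """Buoyant mass (pg) of a sphere: (4πr³/3)(ρ − ρ_f).

    This is the quantity a suspended microchannel resonator measures; it
    converts a density contrast (kg/m³ → 10⁻³ pg/µm³) and a radius (µm)
    into picograms.
    """
    return 4.0 * np.pi * radius_um**3 / 3.0 * (rho_kg_m3 - rho_f_kg_m3) * 1e-3


def radius_from_buoyant_mass(m_b_pg: float, rho_kg_m3: float, rho_f_kg_m3: float) -> float:
    """Invert the buoyant-mass relation for the radius (µm)."""
    drho = rho_kg_m3 - rho_f_kg_m3
    if drho == 0.0:
        raise ValueError("ρ = ρ_f: buoyant mass is identically zero")
    return float(np.cbrt(3.0 * m_b_pg * 1e3 / (4.0 * np.pi * drho)))


def first_crossing(times, values, threshold: float) -> float | None:
    """First time the piecewise-linear trace reaches ``threshold`` from
    below; linear interpolation between samples; None if never."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape or np.any(np.diff(t) < 0):
        raise ValueError("need matched 1-D traces with monotone time stamps")
    if v.size and v[0] >= threshold:
        return float(t[0])
    idx = np.where((v[:-1] < threshold) & (v[1:] >= threshold))[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    frac = (threshold - v[i]) / (v[i + 1] - v[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def detect_entry_transit(
    times,
    leading_x,
    trailing_x,
    taper_entrance_x: float,
    constriction_entrance_x: float,
    constriction_exit_x: float,
) -> tuple[float | None, float | None]:
    """(entry time, transit time) from edge traces and landmark planes.

    Entry runs from the leading edge reaching the taper-entrance plane to
    the trailing edge reaching the constriction-entrance plane; transit
    from that instant to the trailing edge reaching the exit plane. A
    missing crossing yields None for the affected interval.
    """
    t_start = first_crossing(times, leading_x, taper_entrance_x)
    t_in = first_crossing(times, trailing_x, constriction_entrance_x)
    t_out = first_crossing(times, trailing_x, constriction_exit_x)
    entry = None if t_start is None or t_in is None else t_in - t_start
    transit = None if t_in is None or t_out is None else t_out - t_in
    return entry, transit
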
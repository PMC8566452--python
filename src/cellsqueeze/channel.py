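"""Constricted microchannel geometry.

The channel is a straight duct of constant depth D (the z extent) whose
width (the y extent) narrows from an upstream section to a rectangular
constriction through a 45° tapered entrance, and widens back symmetrically
at the exit. The production geometry ("model3") is the constriction part
alone: entry taper + bore + exit taper plus short straight leads, which is
the domain actually used for cell-passage runs; "model1" embeds it in a
longer upstream/downstream setup, "model2" is an intermediate window and
"model4" keeps only the entry taper. x is periodic, so the leads at both
ends have the same width.

All lengths in µm. The geometry provides an analytic signed wall distance
(used by the node–wall forces) and a voxel solid mask (used by the fluid
solver).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = ["ChannelGeometry", "build_channel", "VARIANTS"]

VARIANTS = ("model1", "model2", "model3", "model4")


@dataclass(frozen=True)
class ChannelGeometry:
    """Piecewise-linear channel: leads, 45° tapers and a constriction."""

    constriction_width: float = 6.0
    depth: float = 15.0
    constriction_length: float = 50.0
    upstream_width: float = 20.0
    lead_length: float = 10.0  # straight lead before the entry taper
    tail_length: float = 10.0  # straight lead after the exit taper
    variant: str = "model3"
    taper_angle_deg: float = 45.0
    has_exit_taper: bool = True
    # derived, set in __post_init__
    taper_length: float = field(init=False)
    length: float = field(init=False)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if min(
            self.constriction_width,
            self.depth,
            self.constriction_length,
            self.lead_length,
            self.tail_length,
        ) <= 0.0 or self.upstream_width <= self.constriction_width:
            raise ValueError("channel dimensions must be positive and nested")
        dh = 0.5 * (self.upstream_width - self.constriction_width)
        tl = dh / np.tan(np.radians(self.taper_angle_deg))
        object.__setattr__(self, "taper_length", tl)
        L = self.lead_length + tl + self.constriction_length + self.tail_length
        if self.has_exit_taper:
            L += tl
        object.__setattr__(self, "length", L)

    # -- landmark planes ----------------------------------------------------
    @property
    def taper_entrance_x(self) -> float:
        return self.lead_length

    @property
    def constriction_entrance_x(self) -> float:
        return self.lead_length + self.taper_length

    @property
    def constriction_exit_x(self) -> float:
        return self.constriction_entrance_x + self.constriction_length

    @property
    def constriction_area(self) -> float:
        """Cross-section of the constriction, width × depth, µm²."""
        return self.constriction_width * self.depth

    # -- half-width profile -------------------------------------------------
    def half_width(self, x: float) -> float:
        hu = 0.5 * self.upstream_width
        hc = 0.5 * self.constriction_width
        x1 = self.taper_entrance_x
        x2 = self.constriction_entrance_x
        x3 = self.constriction_exit_x
        x4 = x3 + (self.taper_length if self.has_exit_taper else 0.0)
        if x < x1:
            return hu
        if x < x2:
            return hu + (hc - hu) * (x - x1) / (x2 - x1)
        if x < x3:
            return hc
        if self.has_exit_taper and x < x4:
            return hc + (hu - hc) * (x - x3) / (x4 - x3)
        return hu if self.has_exit_taper else hc

    def side_segments(self) -> np.ndarray:
        """(n, 4) array of (x0, y0, x1, y1) segments of the +y wall polyline."""
        hu = 0.5 * self.upstream_width
        hc = 0.5 * self.constriction_width
        x1 = self.taper_entrance_x
        x2 = self.constriction_entrance_x
        x3 = self.constriction_exit_x
        segs = [(0.0, hu, x1, hu), (x1, hu, x2, hc), (x2, hc, x3, hc)]
        if self.has_exit_taper:
            x4 = x3 + self.taper_length
            segs += [(x3, hc, x4, hu), (x4, hu, self.length, hu)]
        else:
            segs += [(x3, hc, self.length, hc)]
        return np.array(segs, dtype=np.float64)

    # -- queries ------------------------------------------------------------
    def wall_distance(self, position) -> tuple[float, np.ndarray]:
        """Distance to the nearest wall and the wall→fluid unit direction.

        Negative distance flags penetration into the solid. Exact ties are
        broken toward the first wall patch in the fixed order (side
        segments upstream→downstream, then floor, then ceiling).
        """
        x, y, z = (float(v) for v in position)
        d, mx, my, mz = _kernels.wall_distance(x, y, z, self.side_segments(), self.depth)
        return d, np.array([mx, my, mz])

    def contains(self, position) -> bool:
        d, _ = self.wall_distance(position)
        return d > 0.0

    def solid_mask(self, dx: float) -> np.ndarray:
        """Boolean solid mask on a lattice of spacing ``dx``.

        Site centers sit at ((i+½)dx, (j+½)dx − W/2 ... ), i.e. the domain
        spans x ∈ [0, L) periodically, y is centered on the channel axis
        with one solid boundary layer on each side, z ∈ [0, depth] plus one
        solid layer at floor and ceiling. A site is solid when its center
        is outside the fluid region.
        """
        if self.constriction_width < 3.0 * dx:
            raise ValueError(
                f"constriction width {self.constriction_width} µm under-resolved "
                f"at dx = {dx} µm (needs ≥ 3 sites)"
            )
        nx = int(round(self.length / dx))
        ny = int(np.ceil(self.upstream_width / dx)) + 2
        nz = int(np.ceil(self.depth / dx)) + 2
        xs = (np.arange(nx) + 0.5) * dx
        ys = (np.arange(ny) + 0.5) * dx - 0.5 * ny * dx  # centered on axis
        zs = (np.arange(nz) + 0.5) * dx - dx  # one layer below the floor
        hw = np.array([self.half_width(x) for x in xs])
        solid = np.zeros((nx, ny, nz), dtype=np.bool_)
        solid |= np.abs(ys)[None, :, None] > hw[:, None, None]
        solid |= (zs[None, None, :] < 0.0) | (zs[None, None, :] > self.depth)
        return solid

    def lattice_origin(self, dx: float) -> np.ndarray:
        """Physical coordinates of lattice site (0, 0, 0)'s center."""
        ny = int(np.ceil(self.upstream_width / dx)) + 2
        return np.array([0.5 * dx, (0.5 - 0.5 * ny) * dx, -0.5 * dx])


def build_channel(variant: str = "model3", **overrides) -> ChannelGeometry:
    """Construct a geometry variant.

    model1: long leads and a wide upstream setup (full passage).
    model2: a window of model1 with shorter leads.
    model3 (default, the production domain): the constriction part alone.
    model4: entry taper and a short piece of bore only, no exit taper.
    """
    presets = {
        "model1": dict(upstream_width=40.0, lead_length=40.0, tail_length=40.0),
        "model2": dict(upstream_width=30.0, lead_length=20.0, tail_length=20.0),
        "model3": dict(),
        "model4": dict(constriction_length=10.0, has_exit_taper=False,
                       tail_length=1e-9),
    }
    if variant not in presets:
        raise ValueError(f"unknown variant {variant!r}")
    kw = dict(presets[variant])
    kw.update(overrides)
    if variant == "model4" and "tail_length" not in overrides:
        kw["tail_length"] = 0.5  # minimal straight outlet after the truncated bore
    return ChannelGeometry(variant=variant, **kw)
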
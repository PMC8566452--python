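"""Run configuration: plain-text ``key = value`` files over defaults.

Every physical default is the production value of the study setup (time
step 0.01 µs, 1 µm lattice, RPMI 1640 medium properties, the calibrated
reference friction, and the wall-repulsion constants). Unknown keys and
malformed lines are rejected with the offending line number.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class RunConfig:
    # numerics
    dt_us: float = 0.01
    dx_um: float = 1.0
    fluid_substeps: int = 1
    sample_every: int = 25
    seed: int = 0
    vtk_every: int = 0  # 0 = no snapshots
    # fluid / medium (RPMI 1640)
    viscosity_mPas: float = 0.785
    rho_f_kg_m3: float = 1006.0
    xi_ref: float = 0.922
    # cell
    rho_cell_kg_m3: float = 1050.0
    cell_radius_um: float = 6.5
    cell_nodes: int = 393
    # wall interaction
    d_cut_um: float = 0.1
    repulsion_a: float = 0.0001
    repulsion_n: float = 1.2
    mu_f: float = 0.0
    # scenario
    variant: str = "model3"
    flow_rate_uL_h: float = 22.8
    viscous_mode: str = "relative"

    def validate(self) -> "RunConfig":
        if self.dt_us <= 0 or self.dx_um <= 0:
            raise ValueError("dt_us and dx_um must be positive")
        if self.viscous_mode not in ("relative", "literal"):
            raise ValueError(f"unknown viscous_mode {self.viscous_mode!r}")
        if self.variant not in ("model1", "model2", "model3", "model4"):
            raise ValueError(f"unknown variant {self.variant!r}")
        return self


_FIELDS = {f.name: f.type for f in fields(RunConfig)}
_CASTS = {"int": int, "float": float, "str": str}


def load_config(path) -> RunConfig:
    """Parse a key = value config file; defaults fill everything omitted."""
    overrides = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: malformed line {raw.rstrip()!r}")
            key, _, val = (s.strip() for s in line.partition("="))
            if key not in _FIELDS:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            try:
                overrides[key] = _CASTS[_FIELDS[key]](val)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad value for {key}: {exc}")
    return replace(RunConfig(), **overrides).validate()


def dump_config(cfg: RunConfig) -> str:
    """Echo the full effective configuration (rerunnable as a config file)."""
    return "".join(
        f"{f.name} = {getattr(cfg, f.name)}\n" for f in fields(RunConfig)
    )
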
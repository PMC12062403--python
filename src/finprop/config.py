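"""Run configuration: geometry, wave, fluid, grid, timestepping, outputs.

Configurations are plain dataclasses serialisable to/from YAML; the
documented keys mirror the sections below.  ``scale`` selects between
the physical fluid ('physical': artificial seawater around a 57 mm
swimmer) and the reduced desk-scale analogue ('reduced': a target
Reynolds number with the same geometry ratios), which only changes the
nondimensional viscosity the 2-D solver runs at.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .geometry import GeometrySpec
from .kinematics import FinWaveParams
from .metrics import NU_SEAWATER, RHO_SEAWATER

__all__ = ["RunConfig", "GridParams", "FluidParams", "TimesteppingParams",
           "AnalogueParams", "OutputParams", "load_config", "save_config"]


@dataclass(frozen=True)
class FluidParams:
    rho: float = RHO_SEAWATER   # kg/m^3
    nu: float = NU_SEAWATER     # m^2/s


@dataclass(frozen=True)
class GridParams:
    nx: int = 256
    ny: int = 128
    lx: float = 6.0   # body lengths
    ly: float = 3.0

    def __post_init__(self):
        hx, hy = self.lx / self.nx, self.ly / self.ny
        if abs(hx - hy) > 1e-12 * hx:
            raise ValueError("cells must be square")


@dataclass(frozen=True)
class TimesteppingParams:
    steps_per_cycle: int = 200     # dt = T / steps_per_cycle
    n_cycles: float = 10.0
    cfl: float = 0.5
    picard_iters: int = 2
    picard_tol: float = 1e-6
    n_force_iter: int = 2


@dataclass(frozen=True)
class AnalogueParams:
    """Reduction of the 3-D model to the 2-D solver."""

    scale: str = "reduced"        # 'reduced' or 'physical'
    re_target: float = 500.0      # swimming-speed Reynolds number (reduced)
    u_ref_bl_per_cycle: float = 0.073  # expected speed scale, BL per cycle
    head_x: float = 1.5           # head position in the domain, body lengths
    density_ratio: float = 2.0    # body/fluid density of the analogue
    z_cut: float = 0.01           # m, reference cut height of the plane


@dataclass(frozen=True)
class OutputParams:
    directory: str = "out"
    vtk_every: int = 0            # snapshot interval in steps (0 = off)
    write_csv: bool = True


@dataclass(frozen=True)
class RunConfig:
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    wave: FinWaveParams = field(default_factory=FinWaveParams)
    fluid: FluidParams = field(default_factory=FluidParams)
    grid: GridParams = field(default_factory=GridParams)
    timestepping: TimesteppingParams = field(default_factory=TimesteppingParams)
    analogue: AnalogueParams = field(default_factory=AnalogueParams)
    outputs: OutputParams = field(default_factory=OutputParams)
    u_e_target: float = 0.73      # BL/s, measured swimming speed for Eq.-1 style metrics
    seed: int = 0

    # ------------------------------------------------------------------
    def nu_star(self) -> float:
        """Nondimensional viscosity of the analogue run.

        'physical': nu/(L^2 f) — the physical fluid at the model's scale.
        'reduced': u_ref/Re_target with the expected speed in BL/cycle.
        """
        if self.analogue.scale == "physical":
            L = self.geometry.total_length
            return self.fluid.nu / (L ** 2 * self.wave.frequency)
        return self.analogue.u_ref_bl_per_cycle / self.analogue.re_target

    def planar_spec(self):
        from .boundary import PlanarSwimmerSpec
        g = self.geometry
        return PlanarSwimmerSpec.from_geometry(
            total_length=g.total_length, total_width=g.total_width,
            fin_height=g.fin_height, theta_max_deg=self.wave.theta_max,
            caudal_open_angle_deg=g.caudal_open_angle,
            caudal_lobe_span=g.caudal_lobe_span,
            wavelength=self.wave.wavelength,
            ramp_mode=self.wave.ramp_mode)

    def effective_mass(self) -> float:
        """Excess inertia (m - rho*V) of the analogue, nondimensional.

        The displaced area is the elliptical forebody's; a density
        ratio of 2 makes the excess equal to the displaced mass.
        """
        s = self.planar_spec()
        area = np.pi * (s.body_chord / 2.0) * s.half_width
        return (self.analogue.density_ratio - 1.0) * area

    def body_reynolds(self, u_e_bl_s: float = None) -> float:
        """Physical swimming Reynolds number u_e L / nu."""
        u = (u_e_bl_s if u_e_bl_s is not None else self.u_e_target)
        L = self.geometry.total_length
        return u * L * L / self.fluid.nu  # u in BL/s -> m/s is u*L


# ----------------------------------------------------------------------
# YAML (de)serialisation

_SECTIONS = {
    "geometry": GeometrySpec,
    "wave": FinWaveParams,
    "fluid": FluidParams,
    "grid": GridParams,
    "timestepping": TimesteppingParams,
    "analogue": AnalogueParams,
    "outputs": OutputParams,
}


def _as_dict(obj):
    d = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, tuple):
            v = [float(x) for x in v]
        elif isinstance(v, np.integer):
            v = int(v)
        elif isinstance(v, np.floating):
            v = float(v)
        d[f.name] = v
    return d


def config_to_dict(cfg: RunConfig) -> dict:
    out = {name: _as_dict(getattr(cfg, name)) for name in _SECTIONS}
    out["u_e_target"] = cfg.u_e_target
    out["seed"] = cfg.seed
    return out


def config_from_dict(d: dict) -> RunConfig:
    kw = {}
    for name, cls in _SECTIONS.items():
        sect = dict(d.get(name, {}))
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for k, v in sect.items():
            if k not in fields:
                raise ValueError(f"unknown key {k!r} in section {name!r}")
            if isinstance(v, list):
                sect[k] = tuple(v)
        kw[name] = cls(**sect)
    return RunConfig(u_e_target=d.get("u_e_target", 0.73),
                     seed=d.get("seed", 0), **kw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
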
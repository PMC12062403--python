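"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* :func:`gen_track` — 60 fps keypoint tracks of an accelerating or
  cruising 45-57 mm swimmer with seeded Gaussian pixel noise, emulating
  markerless pose-estimation exports, with the closed-form motion
  attached as ground truth;
* :func:`gen_analytic_case` — analytic flow/force fixtures (Taylor-Green
  decay, rigid rotation, planar strain, constant and sinusoidal forcing,
  towed cylinder) whose closed-form solutions serve as test oracles;
* :func:`gen_swim_case` — complete run configurations for the four
  caudal-fin presets (5/30/60/100 degrees) at 10 or 29 Hz, either at the
  physical ('physical') scale — artificial seawater, 57 mm model, 2.6 g —
  or at the reduced desk scale used for paired closed-vs-open
  comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (AnalogueParams, FluidParams, GridParams, OutputParams,
                     RunConfig, TimesteppingParams)
from .geometry import CAUDAL_PRESETS, GeometrySpec
from .kinematics import FinWaveParams
from .velocimetry import TrackSeries

__all__ = ["SyntheticTrackSpec", "gen_track", "gen_analytic_case",
           "gen_swim_case", "AnalyticCase"]


class InvalidSpecError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticTrackSpec:
    """Specification of a synthetic keypoint track.

    ``profile``: 'constant_velocity' (v BL/s), 'constant_acceleration'
    (a BL/s^2) or 'ramp_then_plateau' (a BL/s^2 up to u_max BL/s).
    ``noise_px``: isotropic Gaussian jitter on pixel coordinates, the
    pose-estimation noise proxy.
    """

    profile: str = "constant_velocity"
    v: float = 1.0            # BL/s
    a: float = 0.64           # BL/s^2
    u_max: float = 0.73       # BL/s
    fps: float = 60.0
    duration: float = 2.0     # s
    noise_px: float = 1.0
    scale: float = 5e-4       # m per pixel
    body_length: float = 0.057  # m
    seed: int = 0


def gen_track(spec: SyntheticTrackSpec):
    """Generate a track and its ground truth.

    Returns ``(TrackSeries, truth)`` where ``truth`` holds the noiseless
    speed series (BL/s), final speed, and the spec itself.  Identical
    spec and seed give identical output.
    """
    n = int(round(spec.duration * spec.fps))
    if n < 5:
        raise InvalidSpecError("duration*fps must give at least 5 samples")
    t = np.arange(n) / spec.fps
    BL = spec.body_length
    if spec.profile == "constant_velocity":
        x_m = spec.v * BL * t
        speed = np.full(n, spec.v)
    elif spec.profile == "constant_acceleration":
        x_m = 0.5 * spec.a * BL * t ** 2
        speed = spec.a * t
    elif spec.profile == "ramp_then_plateau":
        t_star = spec.u_max / spec.a
        x_m = np.where(t < t_star, 0.5 * spec.a * BL * t ** 2,
                       0.5 * spec.a * BL * t_star ** 2
                       + spec.u_max * BL * (t - t_star))
        speed = np.minimum(spec.a * t, spec.u_max)
    else:
        raise InvalidSpecError(f"unknown profile {spec.profile!r}")
    y_m = np.zeros(n)
    rng = np.random.default_rng(spec.seed)
    x_px = x_m / spec.scale + rng.normal(0.0, spec.noise_px, n)
    y_px = y_m / spec.scale + rng.normal(0.0, spec.noise_px, n)
    track = TrackSeries(frames=np.arange(n), x=x_px, y=y_px,
                        confidence=np.ones(n), fps=spec.fps,
                        scale=spec.scale, body_length=BL)
    # ground-truth final speed is the continuous-motion value at t=duration
    if spec.profile == "constant_velocity":
        final = spec.v
    elif spec.profile == "constant_acceleration":
        final = spec.a * spec.duration
    else:
        final = min(spec.a * spec.duration, spec.u_max)
    truth = {"speed_bl_s": speed, "final_speed_bl_s": float(final),
             "times": t, "spec": spec, "seed": spec.seed}
    return track, truth


@dataclass(frozen=True)
class AnalyticCase:
    """An analytic fixture: initial data plus its closed-form solution."""

    name: str
    params: dict
    solution: object   # callable; signature depends on the case


def gen_analytic_case(name: str, **params) -> AnalyticCase:
    """Analytic oracles for the flow solver and the propulsion update.

    taylor_green(nu, k):      solution(t) -> kinetic-energy ratio e^{-4 nu k^2 t};
                              velocity components decay as e^{-2 nu k^2 t}.
    rigid_rotation(omega0):   solution(x, y) -> (u, v); vorticity 2*omega0, Q>0.
    planar_strain(a):         u = a x, v = -a y; vorticity 0, Q = -a^2 < 0.
    constant_force(F, m):     solution(t) -> u = F t / m.
    sinusoidal_force(m=1):    F(t) = sin t; solution(t) -> (1 - cos t)/m.
    towed_cylinder(Re):       reference drag-coefficient band for the
                              classical steady-wake regime.
    """
    if name == "taylor_green":
        nu = params.setdefault("nu", 0.05)
        k = params.setdefault("k", 1.0)
        sol = lambda t: np.exp(-4.0 * nu * k ** 2 * t)
    elif name == "rigid_rotation":
        w0 = params.setdefault("omega0", 1.0)
        sol = lambda x, y: (-w0 * y, w0 * x)
    elif name == "planar_strain":
        a = params.setdefault("a", 1.0)
        sol = lambda x, y: (a * x, -a * y)
    elif name == "constant_force":
        F = params.setdefault("F", 1.0)
        m = params.setdefault("m", 1.0)
        sol = lambda t: F * np.asarray(t) / m
    elif name == "sinusoidal_force":
        m = params.setdefault("m", 1.0)
        params.setdefault("force", lambda t: np.sin(t))
        sol = lambda t: (1.0 - np.cos(np.asarray(t))) / m
    elif name == "towed_cylinder":
        params.setdefault("Re", 40.0)
        params.setdefault("cd_reference", 1.5)   # steady-wake regime
        sol = lambda: params["cd_reference"]
    else:
        raise InvalidSpecError(f"unknown analytic case {name!r}")
    return AnalyticCase(name=name, params=params, solution=sol)


#: measured swimming speeds (BL/s) per undulation frequency, and the
#:  expected nondimensional speed scale u_e/(f L) used for Re matching
_CASE_SPEEDS = {10.0: 0.73, 29.0: 2.68}


def gen_swim_case(preset: str, frequency: float = 10.0,
                   scale: str = "reduced", seed: int = 0,
                   **overrides) -> RunConfig:
    """Run configuration for a caudal-fin preset at a given frequency.

    ``preset``: 'closed' (5 deg), 'open30', 'open60' or 'full_open'
    (100 deg).  ``frequency``: 10 Hz (slow) or 29 Hz (fast) — other
    values are allowed and use linear interpolation of the measured
    speed for the expected-speed scale.  ``scale='physical'`` runs the
    physical fluid; 'reduced' targets Re ~ 500 at the 10 Hz speed scale
    (scaled proportionally at other frequencies) so paired comparisons
    finish at desk scale.  Two configs generated for different presets
    differ only in the caudal opening angle.
    """
    if preset not in CAUDAL_PRESETS:
        raise InvalidSpecError(
            f"unknown preset {preset!r}; choose from {sorted(CAUDAL_PRESETS)}")
    phi = CAUDAL_PRESETS[preset]
    u_e = np.interp(frequency, sorted(_CASE_SPEEDS),
                    [_CASE_SPEEDS[k] for k in sorted(_CASE_SPEEDS)])
    u_ref = u_e / frequency     # BL per cycle
    # Reduced-scale Reynolds target: 500 at the 10 Hz case, scaled by the
    # physical Re ratio at other frequencies.
    L = 0.057
    re_10 = _CASE_SPEEDS[10.0] * L * L / 9.5818e-7
    re_phys = u_e * L * L / 9.5818e-7
    re_target = 500.0 * re_phys / re_10
    geometry = GeometrySpec(caudal_open_angle=phi)
    wave = FinWaveParams(frequency=frequency,
                         wavelength=0.55 * geometry.total_length)
    analogue = AnalogueParams(scale=scale, re_target=re_target,
                              u_ref_bl_per_cycle=u_ref)
    n_cycles = overrides.pop("n_cycles", 10.0 if scale == "reduced" else 20.0)
    ts = TimesteppingParams(n_cycles=n_cycles)
    return RunConfig(geometry=geometry, wave=wave, fluid=FluidParams(),
                     grid=GridParams(), timestepping=ts, analogue=analogue,
                     outputs=OutputParams(), u_e_target=float(u_e), seed=seed,
                     **overrides)
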
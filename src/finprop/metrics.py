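"""Hydrodynamic performance statistics for self-propelled swimming.

Implements the acceleration, Reynolds-number, power, efficiency,
cost-of-transport, drag-coefficient and thrust/drag-decomposition
measures used to compare caudal-fin configurations:

* average acceleration  alpha = u_e / t_0  (BL/s^2),
* Reynolds number       Re = u_e L / nu,
* power expenditure     P_e = integral of sum_elements f . v dt,
* Froude efficiency     eta = T_f u_a / P_e,
* cost of transport     Omega = P_e / (u_a m)  (J/(kg m)),
* drag coefficient      C_d = D / (1/2 rho U_a^2 s)  (standard) or the
  first-power ``as_printed`` convention D / (1/2 rho U_a s),
* force decomposition   F = T_f - D, with thrust T_f the sum of
  per-element streamwise force components aligned with the swimming
  direction and drag D the magnitude of the opposing sum (the identity
  holds exactly by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PerformanceSummary",
    "average_acceleration",
    "reynolds",
    "power_expenditure",
    "froude_efficiency",
    "cost_of_transport",
    "drag_coefficient",
    "thrust_drag_split",
    "summarize",
]

#: density of artificial seawater at 24 degC, kg/m^3
RHO_SEAWATER = 1023.6881
#: kinematic viscosity of artificial seawater at 24 degC, m^2/s
NU_SEAWATER = 9.5818e-7
#: reference model length, m
BODY_LENGTH = 0.057


class InvalidInputError(ValueError):
    pass


def average_acceleration(u_e: float, t_0: float) -> float:
    """Average acceleration alpha = u_e / t_0, BL/s^2.

    ``u_e`` is the swimming speed measured in the tank experiment
    (BL/s); ``t_0`` the time the self-propulsion run needs to reach it.
    """
    if t_0 <= 0:
        raise InvalidInputError("t_0 must be positive")
    return u_e / t_0


def reynolds(u_e: float, L: float, nu: float) -> float:
    """Reynolds number u_e * L / nu."""
    if nu <= 0:
        raise InvalidInputError("kinematic viscosity must be positive")
    return u_e * L / nu


def power_expenditure(forces: np.ndarray, velocities: np.ndarray,
                      times: np.ndarray) -> tuple[float, float]:
    """Power delivered by the swimmer surface to the fluid.

    ``forces``: (n_steps, n_elements, ndim) per-element forces the
    surface exerts on the fluid, N.  ``velocities``: matching surface
    velocities, m/s.  ``times``: (n_steps,) s.  Returns ``(total, mean)``:
    the trapezoidal time integral over the window (J) and its time
    average (W).  A 2-D analogue simply carries ndim = 2.
    """
    forces = np.asarray(forces, float)
    velocities = np.asarray(velocities, float)
    times = np.asarray(times, float)
    if forces.shape != velocities.shape or len(times) != len(forces):
        raise InvalidInputError("force and velocity series are misaligned")
    p_inst = np.einsum("sed,sed->s", forces, velocities)
    window = times[-1] - times[0]
    total = float(np.trapezoid(p_inst, times))
    mean = total / window if window > 0 else float(p_inst[0])
    return total, mean


def froude_efficiency(thrust_avg: float, u_a_avg: float, power_avg: float) -> float:
    """eta = T_f * u_a / P_e from cycle-averaged inputs."""
    if power_avg <= 0:
        raise InvalidInputError("average power must be positive for efficiency")
    return thrust_avg * u_a_avg / power_avg


def cost_of_transport(power_avg: float, u_a_avg: float, mass: float) -> float:
    """Omega = P_e / (u_a m), J/(kg m)."""
    if u_a_avg <= 0:
        raise InvalidInputError("average speed must be positive for cost of transport")
    if mass <= 0:
        raise InvalidInputError("mass must be positive")
    return power_avg / (u_a_avg * mass)


def drag_coefficient(drag: float, rho: float, u_a: float, area: float,
                     convention: str = "standard") -> float:
    """Drag coefficient of the swimmer.

    ``standard``: D / (1/2 rho U^2 s).  ``as_printed``: D / (1/2 rho U s)
    — a first-power-of-velocity convention (dimensionally a coefficient
    only together with a unit reference speed); both are provided so
    either bookkeeping can be reproduced, and the convention used is
    recorded in summaries.
    """
    if rho <= 0 or area <= 0:
        raise InvalidInputError("density and area must be positive")
    if u_a == 0:
        raise InvalidInputError("drag coefficient undefined at zero speed")
    if convention == "standard":
        return drag / (0.5 * rho * u_a ** 2 * area)
    if convention == "as_printed":
        return drag / (0.5 * rho * u_a * area)
    raise InvalidInputError(f"unknown convention {convention!r}")


def thrust_drag_split(fx: np.ndarray, swim_sign: float = 1.0):
    """Decompose per-element streamwise forces into thrust and drag.

    ``fx``: per-element force components along +x, on the body.
    ``swim_sign``: +1 if the swimmer moves toward +x, -1 toward -x.
    Thrust T_f sums the components aligned with the swimming direction,
    drag D is the magnitude of the opposing sum; F = T_f - D exactly.
    Returns ``(T_f, D, F)``.
    """
    aligned = swim_sign * np.asarray(fx, float)
    T_f = float(aligned[aligned > 0].sum())
    D = float(-aligned[aligned <= 0].sum())
    return T_f, D, T_f - D


@dataclass
class PerformanceSummary:
    """Cycle-averaged performance statistics over an analysis window."""

    alpha: float            # BL/s^2
    reynolds: float
    froude_efficiency: float
    cost_of_transport: float   # J/(kg m)
    power_avg: float        # W
    drag_coefficient: float
    cd_convention: str
    thrust_avg: float       # N
    drag_avg: float         # N
    net_force_avg: float    # N
    u_e: float              # BL/s, target speed used for alpha
    t_0: float              # s
    u_a_avg: float          # m/s
    u_a_final: float        # m/s
    window: tuple[float, float]  # s
    body_length: float
    mass: float
    extras: dict = field(default_factory=dict)


def summarize(times, u_a, thrust, drag, power,
              u_e_target: float, body_length: float, mass: float,
              rho: float = RHO_SEAWATER, nu: float = NU_SEAWATER,
              area: float = 1.0, cycle: float = None,
              n_cycles: float = 20.0, start_cycle: float = 0.1,
              cd_convention: str = "standard") -> PerformanceSummary:
    """Summarise a propulsion time series into a :class:`PerformanceSummary`.

    Averages run from ``start_cycle`` cycles (the first fraction of a
    cycle is masked: speeds near zero make the drag coefficient and
    cost of transport singular) to ``n_cycles`` cycles, truncated with a
    warning if the series is shorter.  ``u_e_target`` (BL/s) feeds the
    time-to-speed / average-acceleration pathway; alpha * t_0 = u_e by
    construction.
    """
    import warnings as _w
    times = np.asarray(times, float)
    u_a = np.asarray(u_a, float)
    if cycle is None:
        cycle = times[-1] - times[0]
    t_lo = start_cycle * cycle
    t_hi = n_cycles * cycle
    if t_hi > times[-1] + 1e-12:
        _w.warn("averaging window exceeds the series length; truncating")
        t_hi = times[-1]
    m = (times >= t_lo) & (times <= t_hi)
    if m.sum() < 2:
        raise InvalidInputError("fewer than one full cycle of data in the window")
    thrust_avg = float(np.mean(np.asarray(thrust)[m]))
    drag_avg = float(np.mean(np.asarray(drag)[m]))
    power_avg = float(np.mean(np.asarray(power)[m]))
    u_avg = float(np.mean(u_a[m]))

    u_target_ms = u_e_target * body_length
    t_0 = time_to_speed(times, u_a, u_target_ms)
    if t_0 is None:
        alpha = float("nan")
        t_0 = float("nan")
    else:
        alpha = average_acceleration(u_e_target, t_0)
    eta = froude_efficiency(thrust_avg, u_avg, power_avg) if power_avg > 0 else float("nan")
    cot = cost_of_transport(power_avg, u_avg, mass) if u_avg > 0 else float("nan")
    cd = (drag_coefficient(drag_avg, rho, u_avg, area, cd_convention)
          if u_avg > 0 else float("nan"))
    return PerformanceSummary(
        alpha=alpha, reynolds=reynolds(u_avg, body_length, nu),
        froude_efficiency=eta, cost_of_transport=cot, power_avg=power_avg,
        drag_coefficient=cd, cd_convention=cd_convention,
        thrust_avg=thrust_avg, drag_avg=drag_avg,
        net_force_avg=thrust_avg - drag_avg,
        u_e=u_e_target, t_0=t_0, u_a_avg=u_avg, u_a_final=float(u_a[-1]),
        window=(float(t_lo), float(t_hi)), body_length=body_length, mass=mass)


def time_to_speed(times, u_a, u_target: float):
    """First crossing time of ``u_target``, linearly interpolated.

    Returns None if the speed never reaches the target (callers decide
    whether that is an error); the maximum speed reached is available
    from the series itself.
    """
    times = np.asarray(times, float)
    u_a = np.asarray(u_a, float)
    if len(times) == 0:
        raise InvalidInputError("empty series")
    above = u_a >= u_target
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(times[0])
    f = (u_target - u_a[i - 1]) / (u_a[i] - u_a[i - 1])
    return float(times[i - 1] + f * (times[i] - times[i - 1]))
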
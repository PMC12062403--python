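"""Traveling-wave kinematics of the undulating dorsal and anal fins.

The fin surface is driven by an angular excursion wave

    theta(x, t) = beta(t) * theta_max * sin(2*pi*(x/lambda + f*t)),

applied to each fin ray about the fin base line; a point at height ``z``
above the base moves to ``y' = z sin(theta) + y`` while its height
shortens by ``dz = 2 z cos((pi-theta)/2) sin(theta/2)`` (identically
``z (1 - cos theta)``), so fin-ray length is preserved exactly.

The startup coefficient ``beta`` limits the first-cycle excursion.  Two
modes are provided: ``as_printed`` evaluates ``((t-T)^4 + T^4)/T^4`` for
``t <= T`` — note this starts at 2 and decreases to 1, doubling the
startup excursion rather than damping it; ``monotone`` (the default)
uses ``1 - ((T-t)/T)^4``, a true 0-to-1 ramp.  Both are continuous at
``t = T`` and equal to 1 afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ANAL_FIN, DORSAL_FIN, InvalidSpecError, SwimmerGeometry

__all__ = [
    "FinWaveParams",
    "ramp_coefficient",
    "fin_angle",
    "deform_point",
    "deform_surface",
    "fin_edge_displacement",
]


@dataclass(frozen=True)
class FinWaveParams:
    """Fin traveling-wave parameters.

    theta_max: peak angular amplitude, degrees (0, 90).
    wavelength: m (one wavelength along the fin base by default).
    frequency: undulation frequency f, Hz.  The cycle T is 1/f exactly.
    ramp_mode: 'monotone' (0 -> 1 startup ramp) or 'as_printed'.
    The wave travels in the +x direction (head to tail).
    """

    theta_max: float = 30.0
    wavelength: float = 0.031  # m; default: one wavelength over a 57 mm fish's fin base
    frequency: float = 10.0
    ramp_mode: str = "monotone"

    def __post_init__(self):
        if self.frequency <= 0:
            raise InvalidSpecError("frequency must be positive")
        if self.wavelength <= 0:
            raise InvalidSpecError("wavelength must be positive")
        if not (0.0 < self.theta_max < 90.0):
            raise InvalidSpecError("theta_max must be in (0, 90) degrees")
        if self.ramp_mode not in ("as_printed", "monotone"):
            raise InvalidSpecError(f"unknown ramp_mode {self.ramp_mode!r}")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency


def ramp_coefficient(t, T: float, mode: str = "monotone"):
    """Startup coefficient beta(t); dimensionless, 1 for t > T."""
    if T <= 0:
        raise InvalidSpecError("cycle T must be positive")
    t = np.asarray(t, float)
    if mode == "as_printed":
        beta = np.where(t <= T, ((t - T) ** 4 + T ** 4) / T ** 4, 1.0)
    elif mode == "monotone":
        beta = np.where(t <= T, 1.0 - ((T - np.minimum(t, T)) / T) ** 4, 1.0)
    else:
        raise InvalidSpecError(f"unknown ramp_mode {mode!r}")
    return beta if beta.ndim else float(beta)


def fin_angle(x, t: float, params: FinWaveParams):
    """Angular excursion theta(x, t) in degrees."""
    beta = ramp_coefficient(t, params.period, params.ramp_mode)
    phase = 2 * np.pi * (np.asarray(x, float) / params.wavelength
                         + params.frequency * t)
    theta = beta * params.theta_max * np.sin(phase)
    return theta if np.ndim(theta) else float(theta)


def deform_point(y, z, theta):
    """Displace a fin point at (y, z) by ray angle ``theta`` (degrees).

    Returns ``(y', z', dz)``.  ``z`` is the height above the fin base
    line; the mapping is a rotation of the fin ray, so
    ``(y' - y)^2 + z'^2 = z^2`` holds to machine precision.
    """
    th = np.deg2rad(np.asarray(theta, float))
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    yp = z * np.sin(th) + y
    dz = 2.0 * z * np.cos((np.pi - th) / 2) * np.sin(th / 2)
    zp = z - dz
    return yp, zp, dz


def fin_edge_displacement(x, t: float, params: FinWaveParams, H: float):
    """Lateral displacement of the fin's free edge: H*sin(theta(x, t)).

    Drives the planar (2-D) analogue boundary; bounded by
    ``H*sin(theta_max*beta_max)``.
    """
    if H <= 0:
        raise InvalidSpecError("fin height H must be positive")
    return H * np.sin(np.deg2rad(fin_angle(x, t, params)))


def _deformed_vertices(mesh: SwimmerGeometry, t: float, params: FinWaveParams):
    v = mesh.vertices.copy()
    base = mesh.fin_base_z
    for tag, sign in ((DORSAL_FIN, +1.0), (ANAL_FIN, -1.0)):
        idx = np.unique(mesh.triangles[mesh.tags == tag])
        x = v[idx, 0]
        zeta = sign * v[idx, 2] - base          # height above the fin base
        zeta = np.maximum(zeta, 0.0)
        theta = fin_angle(x, t, params)
        yp, zp, _ = deform_point(v[idx, 1], zeta, theta)
        v[idx, 1] = yp
        v[idx, 2] = sign * (base + zp)
    return v


def deform_surface(mesh: SwimmerGeometry, t: float, params: FinWaveParams,
                   velocity: str = "finite_difference",
                   fd_step: float | None = None):
    """Deformed swimmer surface and per-vertex velocities at time ``t``.

    Fin-tagged vertices follow the traveling wave (the same motion is
    applied to the dorsal and anal fins); body and caudal vertices are
    rigid.  Velocities by central finite difference of position (step
    ``T/1000`` by default) or by the analytic chain rule
    (``velocity='analytic'``).
    """
    verts = _deformed_vertices(mesh, t, params)
    if velocity == "finite_difference":
        h = params.period / 1000.0 if fd_step is None else fd_step
        vel = (_deformed_vertices(mesh, t + h, params)
               - _deformed_vertices(mesh, max(t - h, 0.0) if t < h else t - h, params))
        vel /= (2 * h if t >= h else h)
    elif velocity == "analytic":
        vel = _analytic_velocity(mesh, t, params)
    else:
        raise InvalidSpecError(f"unknown velocity mode {velocity!r}")
    return verts, vel


def _analytic_velocity(mesh: SwimmerGeometry, t: float, params: FinWaveParams):
    vel = np.zeros_like(mesh.vertices)
    base = mesh.fin_base_z
    T = params.period
    f = params.frequency
    for tag, sign in ((DORSAL_FIN, +1.0), (ANAL_FIN, -1.0)):
        idx = np.unique(mesh.triangles[mesh.tags == tag])
        x = mesh.vertices[idx, 0]
        zeta = np.maximum(sign * mesh.vertices[idx, 2] - base, 0.0)
        phase = 2 * np.pi * (x / params.wavelength + f * t)
        beta = ramp_coefficient(t, T, params.ramp_mode)
        if t <= T:
            if params.ramp_mode == "as_printed":
                dbeta = 4 * (t - T) ** 3 / T ** 4
            else:
                dbeta = 4 * (T - t) ** 3 / T ** 4
        else:
            dbeta = 0.0
        amp = np.deg2rad(params.theta_max)
        theta = beta * amp * np.sin(phase)
        dtheta = amp * (dbeta * np.sin(phase) + beta * 2 * np.pi * f * np.cos(phase))
        vel[idx, 1] = zeta * np.cos(theta) * dtheta
        vel[idx, 2] = sign * (-zeta * np.sin(theta) * dtheta)
    return vel
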
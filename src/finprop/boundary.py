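"""Planar (2-D) swimmer boundary for the immersed-boundary solver.

The horizontal-plane analogue of the swimmer consists of three marker
groups, all lengths in units of the body length L and time in units of
the undulation cycle T:

* ``body``   — a rigid elliptical forebody (chord ~0.45 L, half-width
  W/2L) that supplies friction and form drag;
* ``fin``    — an undulating filament along the midline aft of the
  body, carrying the median-fin traveling wave: its lateral position is
  ``y(x, t) = env(x) * A * beta(t) * sin(2*pi*(x/lambda + t))`` with
  amplitude A = H sin(theta_max) (the fin's free-edge excursion at the
  cut height) and a smooth envelope from zero at the attachment point;
* ``caudal`` — the caudal fin's in-plane cross-section: two straight
  segments fanning from the peduncle point to the tail tip with
  half-spread w(phi) = r_lobe * sin(phi/2), the lateral offset of the
  folded lobes.  Closed (phi ~ 5 deg) the lobes collapse onto a single
  streamlined centreline spike; open (phi = 100 deg) they form a bluff
  V that sheds a drag (Karman) wake — the in-plane signature of the
  opened fan.

When the lobe spread is below one grid cell the two lobes are merged
into a single centreline segment so that coincident markers do not
double-force the same fluid cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import ramp_coefficient
from .solver import ImmersedBoundary

__all__ = ["PlanarSwimmerSpec", "build_planar_swimmer", "planar_fin_y"]


@dataclass(frozen=True)
class PlanarSwimmerSpec:
    """Geometry of the 2-D analogue, in body-length units.

    Derived from the 3-D model: ``half_width`` = W/2L, ``fin_amplitude``
    = (H/L) sin(theta_max), ``caudal_spread`` = (r_lobe/L) sin(phi/2).
    """

    body_chord: float = 0.45
    half_width: float = 0.0614      # (7 mm / 2) / 57 mm
    fin_start: float = 0.45
    fin_end: float = 0.80
    fin_amplitude: float = 0.105    # (12 mm / 57 mm) * sin(30 deg)
    wavelength: float = 0.55        # one wavelength along the fin
    envelope_frac: float = 0.3      # fraction of fin span used to ramp up
    caudal_start: float = 0.84
    caudal_end: float = 1.0
    caudal_spread: float = 0.0      # w(phi) at the tail tip
    ramp_mode: str = "monotone"

    @classmethod
    def from_geometry(cls, total_length, total_width, fin_height,
                      theta_max_deg, caudal_open_angle_deg,
                      caudal_lobe_span, wavelength=None, **kw):
        L = total_length
        return cls(
            half_width=0.5 * total_width / L,
            fin_amplitude=(fin_height / L) * np.sin(np.deg2rad(theta_max_deg)),
            wavelength=(wavelength / L) if wavelength else 0.55,
            caudal_spread=(caudal_lobe_span / L)
            * np.sin(np.deg2rad(caudal_open_angle_deg) / 2.0),
            **kw)


def _envelope(x, spec: PlanarSwimmerSpec):
    """Smoothstep 0 -> 1 over the first ``envelope_frac`` of the fin."""
    s = (x - spec.fin_start) / ((spec.fin_end - spec.fin_start) * spec.envelope_frac)
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def planar_fin_y(x, t, spec: PlanarSwimmerSpec):
    """Lateral position of the fin filament at time t (cycle units).

    The phase ``x/lambda - t`` makes the wave travel from head (x = 0)
    toward tail (+x), the direction the fins actually pass their wave,
    so the swimmer propels itself head-first toward -x, into the
    body-frame inflow.
    """
    beta = ramp_coefficient(t, 1.0, spec.ramp_mode)
    phase = 2.0 * np.pi * (x / spec.wavelength - t)
    return spec.fin_amplitude * beta * _envelope(x, spec) * np.sin(phase)


def build_planar_swimmer(spec: PlanarSwimmerSpec, t: float, h: float,
                         origin: tuple[float, float],
                         fd_step: float = 1e-3) -> ImmersedBoundary:
    """Marker set for the swimmer at time ``t`` on a grid of spacing ``h``.

    ``origin`` places the head (x=0, y=0 of the body frame) in domain
    coordinates.  Marker spacing targets one grid cell; filament
    velocities come from a central finite difference of position with
    step ``fd_step`` cycles.
    """
    ox, oy = origin
    pts, vel, ds, tags, tans = [], [], [], [], []

    # rigid elliptical forebody
    a, b = spec.body_chord / 2.0, spec.half_width
    perim = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))  # Ramanujan
    M = max(12, int(np.ceil(perim / h)))
    th = np.linspace(0, 2 * np.pi, M, endpoint=False)
    # re-parametrise by arc length so marker spacing is uniform
    thf = np.linspace(0, 2 * np.pi, 20 * M)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(a * np.diff(np.cos(thf)),
                                                    b * np.diff(np.sin(thf))))])
    th = np.interp(np.linspace(0, arc[-1], M, endpoint=False), arc, thf)
    bx = a + a * np.cos(th)
    by = b * np.sin(th)
    pts.append(np.c_[bx, by])
    vel.append(np.zeros((M, 2)))
    ds.append(np.full(M, arc[-1] / M))
    tags.append(np.full(M, "body", dtype=object))
    tx, ty = -a * np.sin(th), b * np.cos(th)
    norm = np.hypot(tx, ty)
    tans.append(np.c_[tx / norm, ty / norm])

    # undulating fin filament
    span = spec.fin_end - spec.fin_start
    Mf = max(8, int(np.ceil(span / h)) + 1)
    xf = np.linspace(spec.fin_start, spec.fin_end, Mf)
    yf = planar_fin_y(xf, t, spec)
    yp = planar_fin_y(xf, t + fd_step, spec)
    ym = planar_fin_y(xf, max(t - fd_step, 0.0), spec)
    denom = (2 * fd_step) if t >= fd_step else fd_step
    vf = (yp - ym) / denom
    seg = np.hypot(np.gradient(xf), np.gradient(yf))
    pts.append(np.c_[xf, yf])
    vel.append(np.c_[np.zeros(Mf), vf])
    ds.append(seg)
    tags.append(np.full(Mf, "fin", dtype=object))
    txf = np.gradient(xf) / seg
    tyf = np.gradient(yf) / seg
    tans.append(np.c_[txf, tyf])

    # caudal fin: V-wedge (or collapsed centreline spike)
    clen = spec.caudal_end - spec.caudal_start
    w_tip = spec.caudal_spread
    lobes = [+1.0, -1.0] if w_tip > h else [0.0]
    for sgn in lobes:
        seg_len = np.hypot(clen, abs(sgn) * w_tip)
        Mc = max(4, int(np.ceil(seg_len / h)) + 1)
        sloc = np.linspace(0.0, 1.0, Mc)
        xc = spec.caudal_start + sloc * clen
        yc = sgn * sloc * w_tip
        pts.append(np.c_[xc, yc])
        vel.append(np.zeros((Mc, 2)))
        ds.append(np.full(Mc, seg_len / (Mc - 1)))
        tags.append(np.full(Mc, "caudal", dtype=object))
        tans.append(np.tile([clen / seg_len, sgn * w_tip / seg_len], (Mc, 1)))

    points = np.concatenate(pts)
    points[:, 0] += ox
    points[:, 1] += oy
    return ImmersedBoundary(points=points,
                            velocities=np.concatenate(vel),
                            element_lengths=np.concatenate(ds),
                            tags=np.concatenate(tags),
                            tangents=np.concatenate(tans))
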
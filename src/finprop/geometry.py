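"""Parametric balistiform swimmer geometry.

Builds a triangulated, region-tagged surface model of a deep-bodied,
laterally compressed median-fin swimmer (body length 57 mm, width 7 mm,
height 40 mm by default) whose caudal fin can be folded open by a
configurable angle ``phi``: ``phi ~ 5 deg`` is the closed (collapsed)
fin, ``phi = 100 deg`` the full-open fan.  Only integral quantities
(surface area, in-plane chords) feed the downstream physics, so the body
outline is an ellipsoid and the fins are thin membrane plates.

Coordinate convention: body frame, ``x`` along the body axis with the
head at ``x = 0`` and the tail at ``x = L``, ``y`` lateral, ``z``
dorsoventral (0 at mid-height).  SI units throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeometrySpec",
    "SwimmerGeometry",
    "PlanarAnalogue",
    "REGION_NAMES",
    "CAUDAL_PRESETS",
    "build_swimmer_geometry",
    "surface_area",
    "planar_analogue",
    "is_watertight",
]

#: Region tag codes used in ``SwimmerGeometry.tags``.
REGION_NAMES = ("body", "dorsal_fin", "anal_fin", "caudal_fin")
BODY, DORSAL_FIN, ANAL_FIN, CAUDAL_FIN = range(4)

#: Caudal-fin opening-angle presets (degrees): closed, two intermediate
#: verification angles, and full-open.
CAUDAL_PRESETS = {"closed": 5.0, "open30": 30.0, "open60": 60.0, "full_open": 100.0}


class InvalidSpecError(ValueError):
    """Raised when geometry parameters are inconsistent or out of range."""


@dataclass(frozen=True)
class GeometrySpec:
    """Parameters defining the swimmer model.

    The default body/fin partition puts the ellipsoidal body at height
    ``total_height - 2*fin_height`` so that body plus dorsal and anal fin
    strips reach ``total_height`` exactly.  The caudal fin consists of two
    fan-shaped lobes hinged on the peduncle (x) axis, folded symmetrically
    out of the vertical plane by ``+-caudal_open_angle/2``; this keeps the
    model width independent of the opening angle.
    """

    total_length: float = 0.057   # m
    total_width: float = 0.007    # m
    total_height: float = 0.040   # m
    caudal_open_angle: float = 5.0  # degrees, in [0, 180)
    fin_height: float = 0.012     # m, H: fin strip extent above its base line
    mass: float = 0.0026          # kg
    # layout fractions of total_length
    body_length_frac: float = 0.84
    fin_span_frac: tuple[float, float] = (0.25, 0.80)
    caudal_lobe_span: float = 0.004   # m, lobe extent from the peduncle axis
    caudal_root_span: float = 0.0004  # m, lobe extent at the peduncle (avoids
    # degenerate apex triangles)
    resolution: int = 24          # azimuthal panels on the body ellipsoid

    def validate(self) -> None:
        for name in ("total_length", "total_width", "total_height",
                     "fin_height", "mass", "caudal_lobe_span"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive, got {getattr(self, name)}")
        if not (0.0 <= self.caudal_open_angle < 180.0):
            raise InvalidSpecError(
                f"caudal_open_angle must be in [0, 180) deg, got {self.caudal_open_angle}")
        if self.total_height <= 2 * self.fin_height:
            raise InvalidSpecError("total_height must exceed twice fin_height")
        if self.resolution < 8:
            raise InvalidSpecError("resolution must be >= 8")


@dataclass
class SwimmerGeometry:
    """Triangulated, region-tagged swimmer surface.

    ``vertices``: (N, 3) float array, m.  ``triangles``: (M, 3) int array
    of vertex indices.  ``tags``: (M,) int array of region codes (see
    :data:`REGION_NAMES`).  The mesh is a disjoint union of closed
    (watertight) components: ellipsoidal body, membrane fin plates.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    tags: np.ndarray
    total_length: float
    total_width: float
    total_height: float
    caudal_open_angle: float
    fin_height: float
    mass: float
    spec: GeometrySpec = field(repr=False, default=None)

    @property
    def fin_base_z(self) -> float:
        """Height of the dorsal-fin base line above the midplane."""
        return 0.5 * self.total_height - self.fin_height

    def bounding_box(self) -> np.ndarray:
        """(2, 3) array of (min, max) corner coordinates."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])


@dataclass(frozen=True)
class PlanarAnalogue:
    """In-plane chords of the swimmer cut by a horizontal plane z = z_cut."""

    body_chord: float          # m
    fin_edge_span: tuple[float, float] | None  # x-interval of the fin cut
    caudal_chord: float        # m, from caudal-tagged elements only
    cut_height: float          # m


# ----------------------------------------------------------------------
# mesh primitives

def _uv_ellipsoid(center, semi_axes, n_az, n_pol):
    """Watertight UV-sphere triangulation scaled to an ellipsoid."""
    cx, cy, cz = center
    a, b, c = semi_axes
    verts = [(cx, cy, cz - c)]           # south pole
    for ip in range(1, n_pol):
        pol = np.pi * ip / n_pol - np.pi / 2  # latitude in (-pi/2, pi/2)
        for ia in range(n_az):
            az = 2 * np.pi * ia / n_az
            verts.append((cx + a * np.cos(pol) * np.cos(az),
                          cy + b * np.cos(pol) * np.sin(az),
                          cz + c * np.sin(pol)))
    verts.append((cx, cy, cz + c))       # north pole
    north = len(verts) - 1
    tris = []

    def ring(ip, ia):
        return 1 + (ip - 1) * n_az + (ia % n_az)

    for ia in range(n_az):               # south cap
        tris.append((0, ring(1, ia + 1), ring(1, ia)))
    for ip in range(1, n_pol - 1):       # bands
        for ia in range(n_az):
            v00, v01 = ring(ip, ia), ring(ip, ia + 1)
            v10, v11 = ring(ip + 1, ia), ring(ip + 1, ia + 1)
            tris.append((v00, v01, v11))
            tris.append((v00, v11, v10))
    for ia in range(n_az):               # north cap
        tris.append((north, ring(n_pol - 1, ia), ring(n_pol - 1, ia + 1)))
    return np.asarray(verts, float), np.asarray(tris, int)


def _pillow_plate(grid_uv, to_xyz):
    """Closed zero-thickness membrane ("pillow") from a structured patch.

    ``grid_uv``: (nu, nv, 2) parameter grid; ``to_xyz`` maps it to (nu, nv, 3)
    coordinates.  Front and back triangle sheets share boundary vertices but
    duplicate interior ones, so every edge is shared by exactly two
    triangles (combinatorially watertight, zero enclosed volume).
    """
    nu, nv = grid_uv.shape[:2]
    if nu < 3 or nv < 3:
        raise ValueError("pillow plate needs at least a 3x3 parameter grid")
    xyz = to_xyz(grid_uv)

    front_idx = np.arange(nu * nv).reshape(nu, nv)
    interior = np.zeros((nu, nv), bool)
    interior[1:-1, 1:-1] = True
    back_idx = front_idx.copy()
    back_idx[interior] = nu * nv + np.arange(interior.sum())
    boundary_flat = ~interior.reshape(-1)

    verts = np.concatenate([xyz.reshape(-1, 3), xyz[interior]])
    tris = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            q = (front_idx[i, j], front_idx[i + 1, j],
                 front_idx[i + 1, j + 1], front_idx[i, j + 1])
            qb = (back_idx[i, j], back_idx[i + 1, j],
                  back_idx[i + 1, j + 1], back_idx[i, j + 1])
            # split along a diagonal with an interior endpoint, so the
            # diagonal edge is not duplicated between front and back sheets
            if boundary_flat[q[0]] and boundary_flat[q[2]]:
                tris.append((q[1], q[2], q[3]))
                tris.append((q[1], q[3], q[0]))
                tris.append((qb[1], qb[3], qb[2]))
                tris.append((qb[1], qb[0], qb[3]))
            else:
                tris.append((q[0], q[1], q[2]))
                tris.append((q[0], q[2], q[3]))
                tris.append((qb[0], qb[2], qb[1]))
                tris.append((qb[0], qb[3], qb[2]))
    return verts, np.asarray(tris, int)


def _rect_plate(x0, x1, z0, z1, nx, nz):
    uv = np.stack(np.meshgrid(np.linspace(x0, x1, nx),
                              np.linspace(z0, z1, nz), indexing="ij"), axis=-1)

    def to_xyz(g):
        out = np.zeros(g.shape[:2] + (3,))
        out[..., 0] = g[..., 0]
        out[..., 2] = g[..., 1]
        return out

    return _pillow_plate(uv, to_xyz)


def _caudal_lobe(spec: GeometrySpec, sign: int, n=12):
    """One caudal lobe: fan-shaped membrane hinged on the peduncle axis.

    Parameterized by (x, r) with r the distance from the axis; the fold by
    ``+-phi/2`` maps r to (y, z) = (r sin(phi/2), +-r cos(phi/2)).
    """
    L = spec.total_length
    x_ped = spec.body_length_frac * L
    chord = L - x_ped
    r0, r1 = spec.caudal_root_span, spec.caudal_lobe_span
    half = np.deg2rad(spec.caudal_open_angle) / 2

    xs = np.linspace(x_ped, L, n)
    uv = np.zeros((n, n, 2))
    for i, x in enumerate(xs):
        rmax = r0 + (r1 - r0) * (x - x_ped) / chord
        uv[i, :, 0] = x
        uv[i, :, 1] = np.linspace(0.0, rmax, n)

    def to_xyz(g):
        out = np.zeros(g.shape[:2] + (3,))
        out[..., 0] = g[..., 0]
        out[..., 1] = g[..., 1] * np.sin(half)
        out[..., 2] = sign * g[..., 1] * np.cos(half)
        return out

    return _pillow_plate(uv, to_xyz)


# ----------------------------------------------------------------------
# public operations

def build_swimmer_geometry(spec: GeometrySpec) -> SwimmerGeometry:
    """Assemble the tagged swimmer surface from a :class:`GeometrySpec`.

    Deterministic for a fixed spec.  Raises :class:`InvalidSpecError` on
    non-positive dimensions or an opening angle outside [0, 180) degrees.
    """
    spec.validate()
    L, W, Hgt, H = (spec.total_length, spec.total_width,
                    spec.total_height, spec.fin_height)
    body_h = Hgt - 2 * H
    Lb = spec.body_length_frac * L
    n_az = spec.resolution
    n_pol = max(8, spec.resolution // 2)

    parts = []
    bv, bt = _uv_ellipsoid((Lb / 2, 0, 0), (Lb / 2, W / 2, body_h / 2), n_az, n_pol)
    parts.append((bv, bt, BODY))

    xf0, xf1 = (f * L for f in spec.fin_span_frac)
    zb = body_h / 2
    nx = max(6, spec.resolution // 2)
    nz = max(4, spec.resolution // 4)
    dv, dt_ = _rect_plate(xf0, xf1, zb, zb + H, nx, nz)
    parts.append((dv, dt_, DORSAL_FIN))
    av, at = _rect_plate(xf0, xf1, -zb - H, -zb, nx, nz)
    parts.append((av, at, ANAL_FIN))

    for sgn in (+1, -1):
        cv, ct = _caudal_lobe(spec, sgn, n=max(8, spec.resolution // 2))
        parts.append((cv, ct, CAUDAL_FIN))

    verts, tris, tags = [], [], []
    offset = 0
    for v, t, tag in parts:
        verts.append(v)
        tris.append(t + offset)
        tags.append(np.full(len(t), tag))
        offset += len(v)
    return SwimmerGeometry(
        vertices=np.concatenate(verts),
        triangles=np.concatenate(tris),
        tags=np.concatenate(tags),
        total_length=L, total_width=W, total_height=Hgt,
        caudal_open_angle=spec.caudal_open_angle,
        fin_height=H, mass=spec.mass, spec=spec,
    )


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p = vertices[triangles]
    return 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


def surface_area(mesh: SwimmerGeometry, region: int | None = None) -> float:
    """Total (or per-region) surface area: sum of triangle areas, m^2.

    Zero-area (degenerate) triangles are excluded with a warning.  Membrane
    fins are closed zero-thickness sheets, so both faces count — the
    appropriate wetted area for a membrane.
    """
    tris = mesh.triangles if region is None else mesh.triangles[mesh.tags == region]
    areas = triangle_areas(mesh.vertices, tris)
    degenerate = areas <= 0.0
    if degenerate.any():
        warnings.warn(f"excluding {degenerate.sum()} degenerate (zero-area) triangles")
    return float(areas[~degenerate].sum())


def is_watertight(mesh: SwimmerGeometry) -> bool:
    """True iff every edge is shared by exactly two triangles."""
    t = mesh.triangles
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool((counts == 2).all())


def planar_analogue(mesh: SwimmerGeometry, z_cut: float) -> PlanarAnalogue:
    """Cut the swimmer by the horizontal plane ``z = z_cut``.

    Returns in-plane chords per region: the body chord, the x-interval over
    which the undulating (dorsal) fin intersects the plane, and the
    projected caudal-fin chord ``c(phi)`` computed from caudal-tagged
    elements only.  Folding the caudal lobes out of the vertical plane
    shortens the in-plane chord, so ``c(phi)`` is non-increasing in phi.
    """
    zmin, zmax = mesh.vertices[:, 2].min(), mesh.vertices[:, 2].max()
    if not (zmin <= z_cut <= zmax):
        raise ValueError(f"z_cut={z_cut} outside mesh z-extent [{zmin}, {zmax}]")

    def cut_xrange(region):
        tris = mesh.triangles[mesh.tags == region]
        z = mesh.vertices[tris][:, :, 2]
        crosses = (z.min(axis=1) <= z_cut) & (z.max(axis=1) >= z_cut)
        if not crosses.any():
            return None
        xs = []
        for tri in tris[crosses]:
            p = mesh.vertices[tri]
            for a, b in ((0, 1), (1, 2), (2, 0)):
                za, zb = p[a, 2], p[b, 2]
                if (za - z_cut) * (zb - z_cut) <= 0 and za != zb:
                    s = (z_cut - za) / (zb - za)
                    xs.append(p[a, 0] + s * (p[b, 0] - p[a, 0]))
        if not xs:
            return None
        return min(xs), max(xs)

    body = cut_xrange(BODY)
    body_chord = 0.0 if body is None else body[1] - body[0]
    fin_span = cut_xrange(DORSAL_FIN)
    caudal = cut_xrange(CAUDAL_FIN)
    if caudal is None:
        warnings.warn("cut plane misses the caudal fin; caudal_chord = 0")
        caudal_chord = 0.0
    else:
        caudal_chord = caudal[1] - caudal[0]
    return PlanarAnalogue(body_chord=float(body_chord),
                          fin_edge_span=fin_span,
                          caudal_chord=float(caudal_chord),
                          cut_height=float(z_cut))


def with_opening_angle(spec: GeometrySpec, phi: float) -> GeometrySpec:
    """Copy of ``spec`` with a different caudal opening angle."""
    return replace(spec, caudal_open_angle=phi)
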
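"""Lofted solid construction of a girdle scale.

The solid is swept in three zones whose section endpoints are anchored on
the principal boundary curves: horizontal sections through the prismatic
base (exact cross sections of the sheared prism), an elbow fan around the
anterior inflection, and flap sections spanning the hook underside to the
outer hook surface, collapsing at the tip.  Each section is the filleted
BASE contour affinely scaled so that it passes through its two endpoints
and the lateral half-width taken from the XZ crown profile (evaluated at
the section center's height, which keeps a broad cup rim).  The sections
are lofted into a closed triangulated surface, capped with the exact BASE
contour at the bottom and collapsed onto the hook tip at the top.

The degenerate no-hook family (``ScaleParameters.prism``) is built by
direct extrusion, because swept sections are ill-defined for it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .curves import PrincipalCurveSet, build_principal_curves
from .errors import GeometryError, ParameterError
from .params import ScaleParameters

__all__ = ["ScaleMesh", "loft_scale", "apply_ornamentation"]

_MIN_TRI_AREA = 1e-12  # mm^2, degenerate-face threshold


@dataclass
class ScaleMesh:
    """Watertight triangulated scale surface in the canonical local frame."""

    mesh: trimesh.Trimesh
    provenance: str = "external"
    params: ScaleParameters | None = None
    curves: PrincipalCurveSet | None = field(default=None, repr=False)

    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices

    @property
    def faces(self) -> np.ndarray:
        return self.mesh.faces

    @property
    def volume(self) -> float:
        return float(self.mesh.volume)

    def copy(self) -> "ScaleMesh":
        return ScaleMesh(self.mesh.copy(), self.provenance, self.params, self.curves)

    def validate(self) -> "ScaleMesh":
        m = self.mesh
        if not m.is_watertight:
            raise GeometryError("scale mesh is not watertight")
        if m.volume <= 0:
            raise GeometryError("scale mesh has non-positive volume")
        if float(m.area_faces.min(initial=np.inf)) <= _MIN_TRI_AREA:
            raise GeometryError("scale mesh contains degenerate triangles")
        return self


def as_trimesh(mesh) -> trimesh.Trimesh:
    """Accept either a ScaleMesh or a bare trimesh.Trimesh."""
    return mesh.mesh if isinstance(mesh, ScaleMesh) else mesh


# --------------------------------------------------------------------- lofting
def loft_scale(
    params: ScaleParameters,
    n_sections: int = 64,
    n_profile: int = 64,
    curves: PrincipalCurveSet | None = None,
) -> ScaleMesh:
    """Loft the parametric scale solid into a watertight mesh.

    Parameters
    ----------
    n_sections : number of spine stations (>= 4).
    n_profile : number of vertices per section ring (>= 8).
    """
    if n_sections < 4:
        raise ParameterError(f"n_sections must be >= 4, got {n_sections}")
    if n_profile < 8:
        raise ParameterError(f"n_profile must be >= 8, got {n_profile}")
    if curves is None:
        curves = build_principal_curves(params)

    base2d = _resample_closed(curves.base_contour, n_profile)

    if params.is_prismatic:
        return _extrude_prism(params, curves, base2d)

    fb_pairs = _section_endpoints(params, curves, n_sections)
    return _sweep_rings(params, curves, base2d, fb_pairs)


_ELBOW_UNDER_FRAC = 0.15  # underside arc consumed while the elbow fan opens


def _arc_param(poly: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(poly, axis=0), axis=1))])
    return s, poly


def _point_at(poly: np.ndarray, s: np.ndarray, si: float) -> np.ndarray:
    return np.array([np.interp(si, s, poly[:, 0]), np.interp(si, s, poly[:, 1])])


def _section_endpoints(
    params: ScaleParameters, curves: PrincipalCurveSet, n_sections: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Anterior/posterior endpoint pairs (F, B) of each section, base to tip.

    Three zones: horizontal sections through the prismatic base; an elbow
    fan whose posterior end climbs from the inflection height to the apex
    while the anterior end creeps up the start of the hook underside; and
    the hook flap, sections spanning underside to outer surface, matched by
    normalized arc length so that both ends meet at the tip.
    """
    seg = curves.segments
    ant = seg["anterior_straight"]  # f0 -> fi
    under = seg["underside"]  # fi -> tip
    post = np.vstack([seg["posterior_straight"], seg["crown"][1:]])  # b0 -> apex
    outer = seg["outer"]  # apex -> tip

    s_post, _ = _arc_param(post)
    s_under, _ = _arc_param(under)
    s_outer, _ = _arc_param(outer)
    s_ant, _ = _arc_param(ant)

    h1 = params.h1
    # posterior arc position at height h1 (posterior boundary is z-monotone)
    z_post = np.maximum.accumulate(post[:, 1])
    s_post_h1 = float(np.interp(h1, z_post, s_post))

    # zone medial arc lengths -> station allocation
    fi = under[0]
    apex = outer[0]
    tip = under[-1]
    arc1 = float(np.hypot(*(fi - ant[0]))) * 0.5 + h1 * 0.5  # ~ prism medial
    mid_root = 0.5 * (under[int(_ELBOW_UNDER_FRAC * (len(under) - 1))] + apex)
    arc2 = float(np.linalg.norm(mid_root - 0.5 * (fi + _point_at(post, s_post, s_post_h1))))
    arc3 = float(np.linalg.norm(0.5 * (fi + apex) - tip)) * 1.2
    tot = arc1 + arc2 + arc3
    # the flap keeps at least a quarter of the budget: small hooks would
    # otherwise get too few sections to resolve the tip tangent
    n3 = max(n_sections // 4, int(round(n_sections * arc3 / tot)))
    n1 = max(3, int(round((n_sections - n3) * arc1 / (arc1 + arc2))))
    n2 = max(3, n_sections - n1 - n3)

    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    # zone 1: horizontal sections, z in [0, h1)
    z_ant = ant[:, 1]  # monotone 0 -> h1
    for i in range(n1):
        z = h1 * i / n1
        F = _point_at(ant, z_ant, z) if z > 0 else ant[0]
        B = _point_at(post, z_post, z) if z > 0 else post[0]
        pairs.append((F, B))
    # zone 2: elbow fan
    s_under_star = _ELBOW_UNDER_FRAC * s_under[-1]
    for j in range(n2):
        tau = j / n2
        F = _point_at(under, s_under, tau * s_under_star)
        B = _point_at(post, s_post, s_post_h1 + tau * (s_post[-1] - s_post_h1))
        pairs.append((F, B))
    # zone 3: hook flap (sigma=1 is the degenerate tip, excluded); stations
    # cluster toward the tip so the terminal tangent is well resolved
    for k in range(n3):
        sig = math.sin(0.5 * math.pi * k / n3)
        F = _point_at(under, s_under, s_under_star + sig * (s_under[-1] - s_under_star))
        B = _point_at(outer, s_outer, sig * s_outer[-1])
        pairs.append((F, B))
    return pairs


def _sweep_rings(
    params: ScaleParameters,
    curves: PrincipalCurveSet,
    base2d: np.ndarray,
    fb_pairs: list[tuple[np.ndarray, np.ndarray]],
) -> ScaleMesh:
    # Extents of the filleted contour (fillets pull the extremes inward of
    # the nominal diamond vertices); rings are normalized by these so each
    # section passes exactly through its endpoints.
    half_x = float(np.abs(base2d[:, 0]).max())
    half_y = float(np.abs(base2d[:, 1]).max())
    tip2d = curves.segments["underside"][-1]

    rings = []
    for F, B in fb_pairs:
        span = float(np.linalg.norm(F - B))
        if span <= 0:
            raise GeometryError("degenerate section: coincident endpoints")
        ey = (F - B) / span
        # lateral half-width follows the section center's *height*: the hook
        # keeps a broad cup rim instead of tapering to a point
        zeta = float(np.clip(0.5 * (F[1] + B[1]) / params.height, 0.0, 1.0))
        half_w = float(curves.xz_halfwidth(zeta)) * (half_x / (params.width / 2.0))
        sx = half_w / half_x
        sy = span / (2.0 * half_y)
        center = 0.5 * (F + B)
        ey3 = np.array([0.0, ey[0], ey[1]])
        ring = (
            np.array([0.0, center[0], center[1]])
            + np.outer(base2d[:, 0] * sx, np.array([1.0, 0.0, 0.0]))
            + np.outer(base2d[:, 1] * sy, ey3)
        )
        rings.append(ring)

    return _seal_loft(
        rings, tip_point=np.array([0.0, tip2d[0], tip2d[1]]), params=params, curves=curves
    )


def _resample_closed(poly: np.ndarray, n: int) -> np.ndarray:
    closed = np.vstack([poly, poly[:1]])
    d = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    si = np.linspace(0.0, s[-1], n, endpoint=False)
    return np.stack([np.interp(si, s, closed[:, k]) for k in range(2)], axis=1)


def _seal_loft(
    rings: list[np.ndarray],
    tip_point: np.ndarray,
    params: ScaleParameters,
    curves: PrincipalCurveSet,
) -> ScaleMesh:
    m = rings[0].shape[0]
    verts = [np.array([[0.0, 0.0, 0.0]])] + rings + [tip_point[None, :]]
    vertices = np.vstack(verts)
    centroid_idx = 0
    ring_idx = lambda i, k: 1 + i * m + (k % m)  # noqa: E731
    tip_idx = vertices.shape[0] - 1

    faces: list[tuple[int, int, int]] = []
    for k in range(m):  # base cap, outward -Z
        faces.append((centroid_idx, ring_idx(0, k + 1), ring_idx(0, k)))
    for i in range(len(rings) - 1):
        for k in range(m):
            a, b = ring_idx(i, k), ring_idx(i, k + 1)
            c, d = ring_idx(i + 1, k + 1), ring_idx(i + 1, k)
            faces.append((a, b, c))
            faces.append((a, c, d))
    for k in range(m):  # tip fan
        faces.append((ring_idx(len(rings) - 1, k), ring_idx(len(rings) - 1, k + 1), tip_idx))

    mesh = trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    out = ScaleMesh(mesh, provenance="parametric", params=params, curves=curves)
    return out.validate()


def _extrude_prism(
    params: ScaleParameters, curves: PrincipalCurveSet, base2d: np.ndarray
) -> ScaleMesh:
    H = params.height
    m = base2d.shape[0]
    bottom = np.column_stack([base2d, np.zeros(m)])
    top = np.column_stack([base2d, np.full(m, H)])
    vertices = np.vstack([[[0.0, 0.0, 0.0]], bottom, top, [[0.0, 0.0, H]]])
    c0, c1 = 0, vertices.shape[0] - 1
    faces: list[tuple[int, int, int]] = []
    for k in range(m):
        k2 = (k + 1) % m
        faces.append((c0, 1 + k2, 1 + k))  # bottom, -Z
        faces.append((c1, 1 + m + k, 1 + m + k2))  # top, +Z
        faces.append((1 + k, 1 + k2, 1 + m + k2))
        faces.append((1 + k, 1 + m + k2, 1 + m + k))
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return ScaleMesh(mesh, "parametric", params, curves).validate()


# ------------------------------------------------------------- ornamentation
def apply_ornamentation(
    scale: ScaleMesh,
    ridge_spacing: float = 0.040,
    ridge_height: float = 0.004,
    bump_spacing: float = 0.005,
    bump_height: float = 0.005,
) -> ScaleMesh:
    """Optional surface micro-ornamentation as a displacement post-process.

    Adds proximodistal ridges (default 40 um spacing) to dorsal-facing
    vertices and conical micro-bumps (default 5 um) to the posterior face.
    Off by default in every pipeline; printed prototypes omit it.
    """
    mesh = as_trimesh(scale).copy()
    v = mesh.vertices.copy()
    n = mesh.vertex_normals
    dorsal = n[:, 2] > 0.3
    disp = np.zeros(len(v))
    disp[dorsal] = 0.5 * ridge_height * (1.0 + np.cos(2 * np.pi * v[dorsal, 0] / ridge_spacing))
    posterior = (n[:, 1] < -0.3) & (n[:, 2] < 0.5)
    disp[posterior] += (
        0.25
        * bump_height
        * (1.0 + np.cos(2 * np.pi * v[posterior, 0] / bump_spacing))
        * (1.0 + np.cos(2 * np.pi * v[posterior, 2] / bump_spacing))
    )
    mesh.vertices = v + n * disp[:, None]
    return ScaleMesh(mesh, scale.provenance, scale.params, scale.curves)
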
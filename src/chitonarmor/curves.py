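"""Principal scaffolding curves of the parametric scale model.

Three planar sections scaffold the solid: the filleted diamond BASE contour
in the Z=0 plane, the sagittal YZ outline (closed silhouette of the hooked
profile) in the X=0 plane, and the transverse XZ crown profile.  A medial
spine through the YZ outline carries the lofting sections.

All curves are cubic interpolating splines (chord-length parameterized,
clamped where a tangent is part of the model definition) sampled to dense
polylines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import GeometryError, ParameterError
from .params import ScaleParameters

__all__ = ["PrincipalCurveSet", "build_principal_curves", "extract_spine", "fillet_diamond"]


# --------------------------------------------------------------------------- BASE
def fillet_diamond(
    width: float,
    length: float,
    fillet_front: float,
    fillet_side: float,
    n_points: int = 64,
) -> np.ndarray:
    """Closed CCW polyline (n,2) of a diamond with circular-arc corner fillets.

    The diamond has vertices at (0, +-length/2) (front/back, filleted with
    ``fillet_front``) and (+-width/2, 0) (sides, ``fillet_side``).  The
    polyline starts at the front vertex region and is not repeated at the end.
    """
    verts = np.array(
        [
            [0.0, length / 2.0],
            [-width / 2.0, 0.0],
            [0.0, -length / 2.0],
            [width / 2.0, 0.0],
        ]
    )
    radii = [fillet_front, fillet_side, fillet_front, fillet_side]
    n_arc = max(3, n_points // 8)
    if n_arc % 2 == 0:
        n_arc += 1  # odd count puts a sample at the arc midpoint (the extreme)
    pts: list[np.ndarray] = []
    for i in range(4):
        p = verts[i]
        a, b = verts[i - 1], verts[(i + 1) % 4]  # neighbors
        r = radii[i]
        if r <= 0:
            pts.append(p[None, :])
            continue
        u = (a - p) / np.linalg.norm(a - p)
        v = (b - p) / np.linalg.norm(b - p)
        half = 0.5 * math.acos(np.clip(np.dot(u, v), -1.0, 1.0))
        t = r / math.tan(half)  # tangency offset along each edge
        bis = (u + v) / np.linalg.norm(u + v)
        center = p + bis * (r / math.sin(half))
        p0, p1 = p + u * t, p + v * t  # arc endpoints (incoming, outgoing)
        a0 = math.atan2(*(p0 - center)[::-1])
        a1 = math.atan2(*(p1 - center)[::-1])
        # sweep the short way
        da = (a1 - a0 + math.pi) % (2 * math.pi) - math.pi
        ang = a0 + da * np.linspace(0.0, 1.0, n_arc)
        pts.append(center + r * np.stack([np.cos(ang), np.sin(ang)], axis=1))
    poly = np.vstack(pts)
    # CCW orientation (vertices were listed CCW already; keep as safety)
    if _signed_area(poly) < 0:
        poly = poly[::-1]
    return poly


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


# ------------------------------------------------------------------- YZ outline
def _clamped_spline(
    points: np.ndarray, tan0: np.ndarray, tan1: np.ndarray, n: int
) -> np.ndarray:
    """Cubic spline through ``points`` (k,2) with clamped end tangents."""
    d = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(d <= 0):
        raise GeometryError("coincident YZ markers make the outline degenerate")
    t = np.concatenate([[0.0], np.cumsum(d)])
    cs = CubicSpline(t, points, bc_type=((1, tan0), (1, tan1)))
    # cosine-clustered samples resolve the fast tangent turns at the
    # clamped ends (tip tangents in particular)
    u = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, n)))
    return cs(u * t[-1])


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero-length tangent")
    return v / n


@dataclass
class PrincipalCurveSet:
    """Markers and sampled principal curves of one parameter set.

    Attributes
    ----------
    base_contour : (n,2) closed CCW polyline of the BASE section, Z=0 plane.
    yz_outline : (m,2) closed CCW polyline of the full sagittal silhouette
        (base edge included), coordinates (y, z).
    yz_curve : (m2,2) the open part of the YZ outline (base corner to base
        corner over the hook), coordinates (y, z).
    xz_halfwidth : callable zeta in [0,1] -> half-width in mm.
    markers : dict label -> 3-vector (the 20 labelled markers).
    anterior / posterior : open polylines from base corner to hook tip along
        each silhouette edge, used for the medial spine.
    """

    params: ScaleParameters
    base_contour: np.ndarray
    yz_outline: np.ndarray
    yz_curve: np.ndarray
    xz_curve: np.ndarray
    markers: dict[str, np.ndarray]
    anterior: np.ndarray
    posterior: np.ndarray
    xz_halfwidth: object = field(repr=False, default=None)
    segments: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def build_principal_curves(
    params: ScaleParameters, samples_per_segment: int = 120
) -> PrincipalCurveSet:
    """Construct the 20 markers and the three principal curves.

    Raises :class:`ParameterError` for invariant violations (including the
    "non-overlapping geometry" case alpha+beta >= 180) and
    :class:`GeometryError` if the resulting outline self-intersects.
    """
    params.validate_invariants()
    W, L, H = params.width, params.length, params.height
    base = fillet_diamond(W, L, params.fillet_front, params.fillet_side)

    if params.is_prismatic:
        return _prismatic_curves(params, base, samples_per_segment)

    m = params.shear
    beta = math.radians(params.beta_deg)
    up = _unit([m, 1.0])  # basal edge direction, angle beta from horizontal

    # The sagittal (x=0) silhouette spans the *filleted* footprint extent,
    # not the nominal diamond vertices.
    _, L_eff = params.footprint_extents()
    f0 = np.array([L_eff / 2.0, 0.0])  # anterior base corner (y, z)
    b0 = np.array([-L_eff / 2.0, 0.0])  # posterior base corner
    p_fi = f0 + up * (params.h1 / math.sin(beta))  # anterior inflection, z = h1
    z_bi = params.back_inflection_frac * H
    p_bi = b0 + up * (z_bi / math.sin(beta))  # posterior inflection

    theta = math.radians(params.tip_tangent_deg)  # hook-axis angle (negative)
    tip_dir = np.array([math.cos(theta), math.sin(theta)])
    p_tip = np.array([p_fi[0] + params.hook_reach, params.tip_height_frac * H])
    if p_tip[1] <= 0:
        raise ParameterError("tip_height_frac places the hook tip below the base plane")
    p_apex = np.array([p_bi[0] + params.apex_shift_frac * (p_tip[0] - p_bi[0]), H])

    def _mid_bulge(a: np.ndarray, b: np.ndarray, frac: float, sense: float) -> np.ndarray:
        chord = b - a
        n = np.linalg.norm(chord)
        nrm = np.array([-chord[1], chord[0]]) / n * sense  # +90 deg rotation
        return 0.5 * (a + b) + frac * n * nrm

    # positive bulge arches the underside up over the cup hollow (the
    # concave face of the hook looks forward-down)
    p_under = _mid_bulge(p_fi, p_tip, params.under_bulge_frac, +1.0)
    p_bm = _mid_bulge(p_bi, p_apex, params.back_bulge_frac, +1.0)
    # crown marker is derived: it shares the posterior bulge parameter
    p_crown = _mid_bulge(p_apex, p_tip, 0.5 * params.back_bulge_frac, +1.0)

    n = samples_per_segment
    horiz = np.array([1.0, 0.0])
    seg_post = _clamped_spline(np.array([p_bi, p_bm, p_apex]), up, horiz, n)
    seg_hook = _clamped_spline(np.array([p_apex, p_crown, p_tip]), horiz, tip_dir, n)
    seg_under = _clamped_spline(np.array([p_tip, p_under, p_fi]), -tip_dir, -up, n)

    # Closed CCW outline: front corner -> base -> back corner -> posterior ->
    # apex -> hook -> tip -> underside -> front inflection -> front corner.
    yz_open = np.vstack(
        [
            [b0],
            seg_post[:-1] if not np.allclose(b0, p_bi) else seg_post[:-1],
            seg_hook[:-1],
            seg_under,
            [f0],
        ]
    )
    # include the straight posterior and anterior prism edges explicitly
    post_straight = np.linspace(b0, p_bi, 24, endpoint=False)
    ant_straight = np.linspace(p_fi, f0, 24, endpoint=False)[1:]
    yz_open = np.vstack([post_straight, seg_post[:-1], seg_hook[:-1], seg_under, ant_straight, [f0]])
    outline = np.vstack([np.linspace(f0, b0, 8, endpoint=False), yz_open[:-1]])

    if _self_intersects(outline):
        raise GeometryError("YZ outline self-intersects for these parameters")

    anterior = np.vstack([[f0], ant_straight[::-1][1:], [p_fi], seg_under[::-1][1:]])
    posterior = np.vstack([post_straight, seg_post[:-1], seg_hook])
    segments = {
        "anterior_straight": np.vstack([[f0], ant_straight[::-1][1:], [p_fi]]),
        "underside": seg_under[::-1],  # fi -> under -> tip
        "posterior_straight": np.vstack([post_straight, [p_bi]]),
        "crown": seg_post,  # bi -> back_mid -> apex
        "outer": seg_hook,  # apex -> crown -> tip
    }

    # ------------------------------------------------------------------ XZ
    sw, sh = params.shoulder_width_frac, params.shoulder_height_frac
    gamma = params.crown_roundness
    from scipy.interpolate import PchipInterpolator

    g = PchipInterpolator([0.0, sh, 1.0], [1.0, sw, 0.0])

    def xz_halfwidth(zeta):
        zeta = np.clip(zeta, 0.0, 1.0)
        return (W / 2.0) * np.power(np.clip(g(zeta), 0.0, None), gamma)

    zs = np.linspace(0.0, 1.0, 2 * n)
    xh = xz_halfwidth(zs)
    xz_curve = np.vstack(
        [
            np.stack([-xh[::-1], zs[::-1] * H], axis=1),
            np.stack([xh[1:], zs[1:] * H], axis=1),
        ]
    )

    yc = 0.0  # XZ section station: spine midplane (markers only)
    markers = _base_markers(params) | {
        "yz_back_inflection": np.array([0.0, *p_bi]),
        "yz_back_mid": np.array([0.0, *p_bm]),
        "yz_apex": np.array([0.0, *p_apex]),
        "yz_crown": np.array([0.0, *p_crown]),
        "yz_tip": np.array([0.0, *p_tip]),
        "yz_under": np.array([0.0, *p_under]),
        "yz_front_inflection": np.array([0.0, *p_fi]),
        "xz_base_left": np.array([-W / 2.0, yc, 0.0]),
        "xz_base_right": np.array([W / 2.0, yc, 0.0]),
        "xz_shoulder_left": np.array([-sw * W / 2.0, yc, sh * H]),
        "xz_shoulder_right": np.array([sw * W / 2.0, yc, sh * H]),
        "xz_crown": np.array([0.0, yc, H]),
    }

    return PrincipalCurveSet(
        params=params,
        base_contour=base,
        yz_outline=outline,
        yz_curve=yz_open,
        xz_curve=xz_curve,
        markers=markers,
        anterior=anterior,
        posterior=posterior,
        xz_halfwidth=xz_halfwidth,
        segments=segments,
    )


def _base_markers(params: ScaleParameters) -> dict[str, np.ndarray]:
    W, L = params.width, params.length
    mk = {
        "base_front": np.array([0.0, L / 2.0, 0.0]),
        "base_back": np.array([0.0, -L / 2.0, 0.0]),
        "base_left": np.array([-W / 2.0, 0.0, 0.0]),
        "base_right": np.array([W / 2.0, 0.0, 0.0]),
    }
    # fillet arc midpoints: on the corner bisector at distance depending on r
    for name, vert, which in (
        ("fillet_front_mid", mk["base_front"], "front"),
        ("fillet_back_mid", mk["base_back"], "front"),
        ("fillet_left_mid", mk["base_left"], "side"),
        ("fillet_right_mid", mk["base_right"], "side"),
    ):
        r = params.fillet_front if which == "front" else params.fillet_side
        half = (
            math.atan2(W / 2.0, L / 2.0) if which == "front" else math.atan2(L / 2.0, W / 2.0)
        )
        # distance from vertex to arc midpoint along the inward bisector
        d = (r / math.sin(half)) - r if r > 0 else 0.0
        direction = -vert[:2] / np.linalg.norm(vert[:2])
        mk[name] = np.array([*(vert[:2] + direction * d), 0.0])
    return mk


def _prismatic_curves(
    params: ScaleParameters, base: np.ndarray, n: int
) -> PrincipalCurveSet:
    """Degenerate family: vertical extrusion of BASE (right prism)."""
    W, L, H = params.width, params.length, params.height
    f0, b0 = np.array([L / 2.0, 0.0]), np.array([-L / 2.0, 0.0])
    front = np.stack([np.full(n, L / 2.0), np.linspace(0.0, H, n)], axis=1)
    back = np.stack([np.full(n, -L / 2.0), np.linspace(0.0, H, n)], axis=1)
    top = np.stack([np.linspace(-L / 2.0, L / 2.0, 8), np.full(8, H)], axis=1)
    yz_open = np.vstack([back, top[1:-1], front[::-1]])
    outline = np.vstack([np.linspace(f0, b0, 8, endpoint=False), yz_open])

    def xz_halfwidth(zeta):
        return np.full_like(np.asarray(zeta, dtype=float), W / 2.0)

    xz_curve = np.array([[-W / 2, 0.0], [-W / 2, H], [W / 2, H], [W / 2, 0.0]])
    markers = _base_markers(params) | {
        "yz_back_inflection": np.array([0.0, -L / 2.0, H / 2.0]),
        "yz_back_mid": np.array([0.0, -L / 2.0, 0.75 * H]),
        "yz_apex": np.array([0.0, -L / 2.0, H]),
        "yz_crown": np.array([0.0, 0.0, H]),
        "yz_tip": np.array([0.0, L / 2.0, H]),
        "yz_under": np.array([0.0, L / 2.0, 0.75 * H]),
        "yz_front_inflection": np.array([0.0, L / 2.0, H / 2.0]),
        "xz_base_left": np.array([-W / 2.0, 0.0, 0.0]),
        "xz_base_right": np.array([W / 2.0, 0.0, 0.0]),
        "xz_shoulder_left": np.array([-W / 2.0, 0.0, H / 2.0]),
        "xz_shoulder_right": np.array([W / 2.0, 0.0, H / 2.0]),
        "xz_crown": np.array([0.0, 0.0, H]),
    }
    return PrincipalCurveSet(
        params=params,
        base_contour=base,
        yz_outline=outline,
        yz_curve=yz_open,
        xz_curve=xz_curve,
        markers=markers,
        anterior=front,
        posterior=back,
        xz_halfwidth=xz_halfwidth,
    )


def _self_intersects(poly: np.ndarray) -> bool:
    from shapely.geometry import Polygon

    return not Polygon(poly).is_valid


# ----------------------------------------------------------------------- spine
def _resample_by_arclength(poly: np.ndarray, n: int) -> np.ndarray:
    d = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    if s[-1] <= 0:
        raise GeometryError("cannot resample a zero-length polyline")
    si = np.linspace(0.0, s[-1], n)
    out = np.empty((n, poly.shape[1]))
    for k in range(poly.shape[1]):
        out[:, k] = np.interp(si, s, poly[:, k])
    return out


def extract_spine(curves: PrincipalCurveSet, n: int = 400) -> np.ndarray:
    """Medial polyline (n,2) of the YZ outline, base midpoint to hook tip.

    The spine follows the medial line of the prismatic base up to the
    anterior inflection height, then the medial curve of the hook flap
    (pointwise midpoints of the underside and the outer hook surface,
    matched by normalized arc length from the tip).  For a straight prism
    this is a vertical segment of length H.
    """
    from shapely.geometry import Polygon

    if not Polygon(curves.yz_outline).is_valid:
        raise GeometryError("self-intersecting YZ outline; cannot extract spine")

    params = curves.params
    if params.is_prismatic or not curves.segments:
        a = _resample_by_arclength(curves.anterior, n)
        p = _resample_by_arclength(curves.posterior, n)
        return _resample_by_arclength(0.5 * (a + p), n)

    import math as _math

    beta = _math.radians(params.beta_deg)
    up = np.array([_math.cos(beta), _math.sin(beta)])
    t_h1 = params.h1 / _math.sin(beta)
    prism_med = np.outer(np.linspace(0.0, t_h1, n // 3), up)

    k = n // 2
    under = _resample_by_arclength(curves.segments["underside"], k)  # fi -> tip
    outer = _resample_by_arclength(curves.segments["outer"], k)  # apex -> tip
    flap_med = 0.5 * (under + outer)

    spine = np.vstack([prism_med, flap_med])
    spine = _resample_by_arclength(spine, n)
    # light smoothing of the prism->flap junction, endpoints pinned
    w = max(3, n // 60)
    kern = np.ones(w) / w
    sm = np.stack(
        [
            np.convolve(np.pad(spine[:, j], (w // 2, w // 2), mode="edge"), kern, "valid")
            for j in range(2)
        ],
        axis=1,
    )
    sm[0], sm[-1] = spine[0], spine[-1]
    return _resample_by_arclength(sm, n)
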
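"""Mesh-based morphometrics of girdle scales.

All descriptors are measured from two silhouette projections of the closed
scale mesh, mirroring how they are defined on micro-CT derived geometry:

* transverse contour — silhouette along X onto the (Y, Z) plane; carries the
  heights h1/h2/H, the inclination angle beta (posterior basal edge), the
  imbrication angle alpha (interior angle at the anterior inflection between
  the downward basal direction and the hook axis, i.e. the tip tangent of
  the anterior silhouette chain), and the overlap split A1 / A2.
* bottom contour — silhouette along -Z onto the (X, Y) plane; carries the
  base width W and length L.

Volume and volume centroid come from the divergence theorem on the closed
mesh (via trimesh).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .errors import GeometryError
from .loft import ScaleMesh, as_trimesh

__all__ = [
    "MorphometricRecord",
    "project_contours",
    "measure",
    "basal_com_check",
    "canonicalize",
]

_DEGENERATE_TURN_DEG = 5.0  # total anterior-edge turn below which a scale is a prism


@dataclass
class MorphometricRecord:
    """Descriptor set of one scale (lengths mm, areas mm^2, volume mm^3)."""

    W: float
    L: float
    h1: float
    h2: float
    H: float
    alpha_deg: float
    beta_deg: float
    A1: float
    A2: float
    A_total: float
    V: float
    centroid: np.ndarray
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def H_L(self) -> float:
        return self.H / self.L

    @property
    def W_L(self) -> float:
        return self.W / self.L

    @property
    def h1_H(self) -> float:
        return self.h1 / self.H

    @property
    def overlap_ratio(self) -> float:
        """A1 / A_total, the fraction of silhouette overhanging the base front."""
        return self.A1 / self.A_total

    def as_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in ("W", "L", "h1", "h2", "H", "alpha_deg", "beta_deg", "A1", "A2", "A_total", "V")
        }
        d["centroid_x"], d["centroid_y"], d["centroid_z"] = map(float, self.centroid)
        d["H_L"], d["W_L"], d["h1_H"] = self.H_L, self.W_L, self.h1_H
        d["overlap_ratio"] = self.overlap_ratio
        d["flags"] = list(self.flags)
        return d


# ------------------------------------------------------------------ silhouettes
def _silhouette(triangles: np.ndarray, ax0: int, ax1: int) -> Polygon:
    """Union of projected triangles as a single silhouette polygon."""
    pts = triangles[:, :, (ax0, ax1)]
    # signed double area; drop edge-on triangles
    a = pts[:, 1] - pts[:, 0]
    b = pts[:, 2] - pts[:, 0]
    area2 = np.abs(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
    keep = pts[area2 > 1e-14]
    if keep.size == 0:
        raise GeometryError("mesh projects to zero area")
    polys = shapely.polygons(keep)
    polys = shapely.make_valid(polys)
    merged = unary_union(polys)
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda g: g.area)
    if merged.is_empty or merged.area <= 0:
        raise GeometryError("degenerate silhouette")
    return Polygon(merged.exterior)  # interior voids cannot occur in a silhouette


def project_contours(mesh) -> tuple[Polygon, Polygon]:
    """(transverse, bottom) silhouette polygons of a watertight mesh.

    Transverse = projection along X onto (y, z); bottom = projection along
    -Z onto (x, y).  Both are closed simple polygons.
    """
    tm = as_trimesh(mesh)
    if len(tm.faces) == 0 or not tm.is_watertight:
        raise GeometryError("project_contours requires a non-empty watertight mesh")
    tri = tm.triangles
    transverse = _silhouette(tri, 1, 2)  # (y, z)
    bottom = _silhouette(tri, 0, 1)  # (x, y)
    return transverse, bottom


# ----------------------------------------------------------------- chain tools
def _sagittal_ring(tm) -> np.ndarray:
    """Largest closed loop of the x ~ 0 section, CCW in (y, z)."""
    xs = tm.vertices[:, 0]
    x0 = 1e-6 * max(1.0, float(xs.max() - xs.min()))  # dodge vertex coincidences
    sec = tm.section(plane_origin=[x0, 0.0, 0.0], plane_normal=[1.0, 0.0, 0.0])
    if sec is None:
        raise GeometryError("empty sagittal section")
    loops = [np.asarray(d) for d in sec.discrete]
    loop = max(loops, key=lambda a: Polygon(a[:, 1:]).area if len(a) > 3 else 0.0)
    ring = loop[:, 1:]  # (y, z)
    if np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    poly = Polygon(ring)
    if not poly.is_valid:
        # tolerate micro-slivers from near-degenerate section crossings
        fixed = shapely.make_valid(poly)
        geoms = getattr(fixed, "geoms", [fixed])
        polys = [g for g in geoms if g.geom_type == "Polygon"]
        if not polys:
            raise GeometryError("degenerate sagittal section")
        poly = max(polys, key=lambda g: g.area)
    if poly.area <= 0:
        raise GeometryError("degenerate sagittal section")
    return _ring_coords(poly)


def _ring_coords(poly: Polygon) -> np.ndarray:
    c = np.asarray(shapely.geometry.polygon.orient(poly).exterior.coords)[:-1]
    return c


def _chain_between(ring: np.ndarray, i_from: int, i_to: int, avoid: int) -> np.ndarray:
    """Vertices of the ring boundary from i_from to i_to not passing ``avoid``."""
    n = len(ring)
    fwd = [(i_from + k) % n for k in range((i_to - i_from) % n + 1)]
    bwd = [(i_from - k) % n for k in range((i_from - i_to) % n + 1)]
    chain = fwd if avoid not in fwd[1:-1] else bwd
    return ring[np.array(chain)]


def _resample(poly: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    d = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    si = np.linspace(0.0, s[-1], n)
    out = np.stack([np.interp(si, s, poly[:, k]) for k in range(2)], axis=1)
    return out, si


def _smooth(x: np.ndarray, w: int = 5) -> np.ndarray:
    k = np.ones(w) / w
    return np.convolve(np.pad(x, (w // 2, w // 2), mode="edge"), k, mode="valid")


# -------------------------------------------------------------------- measure
def measure(mesh, pose: str = "canonical") -> MorphometricRecord:
    """Measure the full descriptor set from a watertight scale mesh.

    pose="auto" re-poses an arbitrarily oriented mesh into the canonical
    frame first (PCA of the base footprint, hook side toward +Y).
    """
    tm = as_trimesh(mesh)
    if pose == "auto":
        tm = canonicalize(tm)
    if not tm.is_watertight:
        raise GeometryError("measure requires a watertight mesh")

    transverse, bottom = project_contours(tm)
    H = float(tm.vertices[:, 2].max() - tm.vertices[:, 2].min())
    zb = float(tm.vertices[:, 2].min())
    ztol = zb + max(1e-9, 1e-3 * H)

    # W and L are the extents of the *base* footprint (the basal slice of
    # the bottom contour); for strongly imbricated scales the full bottom
    # silhouette also contains the hook overhang.
    vb = tm.vertices[tm.vertices[:, 2] <= ztol]
    W = float(vb[:, 0].max() - vb[:, 0].min())
    L = float(vb[:, 1].max() - vb[:, 1].min())

    # h1, alpha, beta live on the sagittal (x ~ 0) section outline: the
    # projected silhouette of a cup-like hook is bounded by the lateral rim
    # envelope near the tip, which hides the hook axis.
    ring = _sagittal_ring(tm)
    flags: list[str] = []

    base_idx = np.where(ring[:, 1] <= ztol)[0]
    if base_idx.size < 2:
        raise GeometryError("sagittal section has no basal edge")
    i_front = base_idx[np.argmax(ring[base_idx, 0])]
    i_back = base_idx[np.argmin(ring[base_idx, 0])]
    # hook tip: anteriormost point of the section (ties -> highest)
    ymax_t = ring[:, 0].max()
    cand = np.where(ring[:, 0] >= ymax_t - 1e-9 * max(1.0, abs(ymax_t)))[0]
    i_tip = cand[np.argmax(ring[cand, 1])]
    i_apex = int(np.argmax(ring[:, 1]))

    anterior = _chain_between(ring, i_front, i_tip, avoid=i_apex)
    posterior = _chain_between(ring, i_back, i_apex, avoid=i_front)
    outer = _chain_between(ring, i_apex, i_tip, avoid=i_back)

    beta_deg = _fit_basal_angle(posterior, H, zb)
    h1, degenerate = _inflection_height(anterior, H, zb)
    if degenerate:
        alpha_deg = 180.0
        flags.append("degenerate")
    else:
        theta_tip = _tip_tangent_deg(outer, anterior)
        beta = math.radians(beta_deg)
        th = math.radians(theta_tip)
        d_down = np.array([-math.cos(beta), -math.sin(beta)])
        d_tip = np.array([math.cos(th), math.sin(th)])
        alpha_deg = math.degrees(
            math.acos(float(np.clip(np.dot(d_down, d_tip), -1.0, 1.0)))
        )
        if _double_curved(np.vstack([posterior, outer[1:]]), H, zb):
            flags.append("multi-inflection")

    # overlap split: vertical through the anteriormost point of the base
    # footprint
    xmin, ymin, xmax, ymax = bottom.bounds
    y_split = float(vb[:, 1].max())
    big = max(abs(v) for v in (xmin, xmax, ymin, ymax)) + H + 1.0
    a_total = transverse.area
    a1_geom = transverse.intersection(box(y_split, zb - big, big, zb + big))
    A1 = float(a1_geom.area)
    A2 = a_total - A1

    rec = MorphometricRecord(
        W=W,
        L=L,
        h1=h1,
        h2=H - h1,
        H=H,
        alpha_deg=alpha_deg,
        beta_deg=beta_deg,
        A1=A1,
        A2=A2,
        A_total=A1 + A2,
        V=float(tm.volume),
        centroid=np.asarray(tm.center_mass, dtype=float),
        flags=tuple(flags),
    )
    return rec


def _fit_basal_angle(posterior: np.ndarray, H: float, zb: float) -> float:
    """Angle (deg) between the posterior basal edge and the base plane."""
    z = posterior[:, 1] - zb
    sel = (z >= 0.05 * H) & (z <= 0.40 * H)
    pts = posterior[sel] if sel.sum() >= 2 else posterior[: max(3, len(posterior) // 4)]
    pts = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    d = vt[0]
    if d[1] < 0:
        d = -d  # orient upward
    return math.degrees(math.atan2(d[1], d[0])) if d[0] >= 0 else math.degrees(
        math.atan2(d[1], d[0])
    ) % 180.0


def _inflection_height(anterior: np.ndarray, H: float, zb: float) -> tuple[float, bool]:
    """(h1, degenerate) — height where the anterior chain leaves the straight
    basal edge, located where the smoothed curvature magnitude first crosses
    half of its early-hook plateau (the unbiased onset of a smoothed step)."""
    chain, s = _resample(anterior, 512)
    seg = np.diff(chain, axis=0)
    theta = np.unwrap(np.arctan2(seg[:, 1], seg[:, 0]))
    # total variation, not net turn: an S- or step-shaped edge must not
    # cancel to "straight"
    total_turn = math.degrees(float(np.abs(np.diff(_smooth(theta, 5))).sum()))
    if total_turn < _DEGENERATE_TURN_DEG:
        return H, True

    n = len(chain)
    ds = np.diff(s).mean()
    kappa = _smooth(np.gradient(theta, ds), 5)
    kabs = np.abs(kappa)
    kmax = kabs.max()
    # noise floor of the straight basal edge, then the *first* sustained
    # rise above it (not the global curvature peak, which sits at the cup)
    noise = float(np.percentile(kabs[: max(8, int(0.10 * n))], 95))
    tau = max(4.0 * noise, 0.04 * kmax)
    run = max(4, int(0.01 * n))
    sustained = np.convolve((kabs > tau).astype(float), np.ones(run), "valid") >= run
    if not sustained.any():
        return H, True
    j1 = int(np.argmax(sustained))
    # local early-hook plateau; onset = its half crossing
    plateau = float(np.median(kabs[j1 : j1 + max(run, int(0.08 * n))]))
    half = 0.5 * plateau
    j = j1
    while j > 0 and kabs[j - 1] >= half:
        j -= 1
    s0 = float(s[j])
    h1 = float(np.interp(s0, s[:-1], chain[:-1, 1])) - zb
    return float(np.clip(h1, 1e-9, H)), False


def _last_chord(chain: np.ndarray) -> np.ndarray:
    """Unit direction of the final chord, skipping micro-segments."""
    d = np.linalg.norm(np.diff(chain, axis=0), axis=1)
    min_len = 0.01 * d.sum()
    end = chain[-1]
    j = len(chain) - 2
    while j > 0 and np.linalg.norm(end - chain[j]) < min_len:
        j -= 1
    v = end - chain[j]
    n = np.linalg.norm(v)
    if n < 1e-15:  # fully collapsed tail: fall back to the whole chord
        v = end - chain[0]
        n = np.linalg.norm(v)
    if n < 1e-15:  # degenerate chain altogether
        return np.array([1.0, 0.0])
    return v / n


def _tip_tangent_deg(outer: np.ndarray, anterior: np.ndarray) -> float:
    """Hook-axis direction (deg): arrival tangent of the outer hook surface
    at the tip (the terminal chord; meshes cluster sections near the tip,
    making the final chord a good tangent estimate)."""
    del anterior  # kept in the signature for symmetry with the chain split
    v = _last_chord(outer)
    return math.degrees(math.atan2(v[1], v[0]))


def _double_curved(dorsal_chain: np.ndarray, H: float, zb: float, turn_deg: float = 45.0) -> bool:
    """True for the doubly-curved scale class (S-shaped flap axis).

    Measured as integrated turning of the dorsal boundary (posterior edge
    over the crown to the tip) above the basal region: a singly-curved hook
    turns essentially one way; an S-shaped scale accumulates substantial
    turn in both senses.
    """
    sel = dorsal_chain[:, 1] - zb > 0.25 * H
    if sel.sum() < 8:
        return False
    chain, _ = _resample(dorsal_chain[sel], 256)
    seg = np.diff(chain, axis=0)
    theta = np.unwrap(np.arctan2(seg[:, 1], seg[:, 0]))
    dth = np.degrees(np.diff(_smooth(theta, 7)))
    pos = float(dth[dth > 0].sum())
    neg = float(-dth[dth < 0].sum())
    return min(pos, neg) > turn_deg


def basal_com_check(record: MorphometricRecord) -> bool:
    """True iff the volume centroid lies within the basal (prismatic) region."""
    return float(record.centroid[2]) < record.h1


# -------------------------------------------------------------------- posing
def canonicalize(mesh) -> "trimesh.Trimesh":
    """Re-pose an external mesh into the canonical frame.

    Assumes +Z is already the dorsal direction; aligns the base footprint's
    principal axis with Y (PCA), puts the hook side (apex) toward +Y, drops
    the base plane to z=0 and centers the base centroid at the origin.
    """
    import trimesh

    tm = as_trimesh(mesh).copy()
    v = tm.vertices
    zmin = v[:, 2].min()
    zrng = v[:, 2].ptp() if hasattr(v[:, 2], "ptp") else np.ptp(v[:, 2])
    base = v[v[:, 2] <= zmin + 0.05 * zrng][:, :2]
    ctr = base.mean(axis=0)
    u, sv, vt = np.linalg.svd(base - ctr, full_matrices=False)
    major = vt[0]  # footprint length axis -> Y
    R2 = np.array([[major[1], -major[0]], [major[0], major[1]]])
    T = np.eye(4)
    T[:2, :2] = R2
    T[:2, 3] = -R2 @ ctr
    T[2, 3] = -zmin
    tm.apply_transform(T)
    # hook (apex) side toward +Y
    apex_y = tm.vertices[np.argmax(tm.vertices[:, 2]), 1]
    if apex_y < 0:
        F = np.eye(4)
        F[0, 0] = -1.0
        F[1, 1] = -1.0
        tm.apply_transform(F)
    return tm
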
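"""Low-level geometry kernels.

Self-contained implementations of two primitives the rest of the package
leans on: constrained triangulation of polygons-with-holes (ear clipping
with hole bridging) used for mesh caps, and vectorized point-triangle /
mesh-mesh minimum distance queries used for contact detection.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .errors import GeometryError

__all__ = ["triangulate_polygon", "point_triangle_distance", "mesh_min_distance"]


# ---------------------------------------------------------------- ear clipping
def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _point_in_tri_strict(p, a, b, c, eps=1e-12) -> bool:
    """Strict interior test (boundary points do not count)."""
    d1 = _cross(a, b, p)
    d2 = _cross(b, c, p)
    d3 = _cross(c, a, p)
    return (d1 > eps) and (d2 > eps) and (d3 > eps)


def _ring(coords) -> list[np.ndarray]:
    pts = [np.asarray(c, dtype=float) for c in coords]
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    return pts


def _bridge_holes(outer: list[np.ndarray], holes: list[list[np.ndarray]]) -> list[np.ndarray]:
    """Merge holes into the outer ring via mutually visible bridge vertices."""
    poly = list(outer)
    # process holes right-to-left by their rightmost vertex
    for hole in sorted(holes, key=lambda h: -max(p[0] for p in h)):
        hi = int(np.argmax([p[0] for p in hole]))
        m = hole[hi]
        # candidate outer vertex: nearest visible vertex to the right of m
        best, best_d = None, np.inf
        for j, q in enumerate(poly):
            if q[0] < m[0]:
                continue
            d = np.hypot(*(q - m))
            if d < best_d and _segment_clear(m, q, poly, hole):
                best, best_d = j, d
        if best is None:  # fall back to globally nearest vertex
            best = int(np.argmin([np.hypot(*(q - m)) for q in poly]))
        # splice: outer[..best] + [hole[hi..], hole[..hi], hole[hi]] + outer[best..]
        hole_cycle = hole[hi:] + hole[:hi] + [hole[hi]]
        poly = poly[: best + 1] + hole_cycle + poly[best:]
    return poly


def _segment_clear(a, b, *rings) -> bool:
    ab = np.asarray(b) - np.asarray(a)
    ab2 = float(ab @ ab)
    for ring in rings:
        n = len(ring)
        for i in range(n):
            p, q = ring[i], ring[(i + 1) % n]
            if _segments_intersect(a, b, p, q):
                return False
        # a bridge passing exactly through a vertex still splices a
        # self-crossing ring: reject those too
        if ab2 > 0:
            for r in ring:
                if np.allclose(r, a) or np.allclose(r, b):
                    continue
                t = float((np.asarray(r) - a) @ ab) / ab2
                if 0.0 < t < 1.0:
                    closest = np.asarray(a) + t * ab
                    if np.hypot(*(closest - r)) < 1e-9 * math.sqrt(ab2):
                        return False
    return True


def _segments_intersect(a, b, p, q, eps=1e-12) -> bool:
    """Proper intersection test, ignoring shared endpoints."""
    for e in (p, q):
        if np.allclose(a, e) or np.allclose(b, e):
            return False
    d1 = _cross(a, b, p)
    d2 = _cross(a, b, q)
    d3 = _cross(p, q, a)
    d4 = _cross(p, q, b)
    return (d1 * d2 < -eps) and (d3 * d4 < -eps)


def triangulate_polygon(poly: Polygon) -> tuple[np.ndarray, np.ndarray]:
    """Ear-clip a (possibly holed) polygon into (vertices (n,2), faces (m,3)).

    All boundary vertices are preserved in order, so triangulated caps stitch
    watertightly onto wall strips built from the same rings.
    """
    if poly.is_empty or poly.area <= 0:
        raise GeometryError("cannot triangulate an empty polygon")
    from shapely.geometry.polygon import orient

    poly = orient(poly)  # exterior CCW, holes CW
    outer = _ring(poly.exterior.coords)
    holes = [_ring(h.coords) for h in poly.interiors]
    verts = _bridge_holes(outer, holes) if holes else list(outer)

    n = len(verts)
    idx = list(range(n))
    vcoords = np.array(verts)
    faces: list[tuple[int, int, int]] = []
    guard = 0
    while len(idx) > 3:
        guard += 1
        if guard > 4 * n * n:
            raise GeometryError("ear clipping failed to converge")
        n_cur = len(idx)
        found = False
        for k in range(n_cur):
            i0, i1, i2 = idx[k - 1], idx[k], idx[(k + 1) % n_cur]
            a, b, c = vcoords[i0], vcoords[i1], vcoords[i2]
            if _cross(a, b, c) <= 1e-14:  # reflex or collinear: not an ear
                continue
            ok = True
            for j in idx:
                if j in (i0, i1, i2):
                    continue
                p = vcoords[j]
                # duplicated bridge vertices coincide with ear corners; they
                # sit on the boundary and must not block the ear
                if (
                    np.array_equal(p, a)
                    or np.array_equal(p, b)
                    or np.array_equal(p, c)
                ):
                    continue
                if _point_in_tri_strict(p, a, b, c):
                    ok = False
                    break
            if ok:
                faces.append((i0, i1, i2))
                idx.pop(k)
                found = True
                break
        if not found:
            # numerical fallback: clip the least-reflex vertex
            k = int(
                np.argmax(
                    [
                        _cross(
                            vcoords[idx[k - 1]],
                            vcoords[idx[k]],
                            vcoords[idx[(k + 1) % len(idx)]],
                        )
                        for k in range(len(idx))
                    ]
                )
            )
            faces.append((idx[k - 1], idx[k], idx[(k + 1) % len(idx)]))
            idx.pop(k)
    faces.append((idx[0], idx[1], idx[2]))
    return vcoords, np.array(faces, dtype=np.int64)


# ------------------------------------------------------- point-triangle query
def point_triangle_distance(points: np.ndarray, tris: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min distance from each point to its paired triangle.

    points: (n,3); tris: (n,3,3).  Returns (distances (n,), closest (n,3)).
    Standard region-based closest-point computation, fully vectorized.
    """
    B = tris[:, 0]
    E0 = tris[:, 1] - B
    E1 = tris[:, 2] - B
    D = B - points
    a = np.einsum("ij,ij->i", E0, E0)
    b = np.einsum("ij,ij->i", E0, E1)
    c = np.einsum("ij,ij->i", E1, E1)
    d = np.einsum("ij,ij->i", E0, D)
    e = np.einsum("ij,ij->i", E1, D)
    det = np.maximum(a * c - b * b, 1e-30)
    s = b * e - c * d
    t = b * d - a * e

    s_out = np.empty_like(s)
    t_out = np.empty_like(t)

    inside = (s + t <= det) & (s >= 0) & (t >= 0)
    s_out[inside] = s[inside] / det[inside]
    t_out[inside] = t[inside] / det[inside]

    def clamp01(x):
        return np.clip(x, 0.0, 1.0)

    # edge/vertex regions, resolved per point
    rem = ~inside
    if rem.any():
        ar, br, cr, dr, er = a[rem], b[rem], c[rem], d[rem], e[rem]
        sr, tr = s[rem], t[rem]
        detr = det[rem]
        s2 = np.zeros_like(ar)
        t2 = np.zeros_like(ar)

        # region decomposition (Eberly)
        reg4 = (sr < 0) & (tr < 0)
        reg3 = (sr < 0) & (tr >= 0) & ~reg4
        reg5 = (tr < 0) & (sr >= 0)
        reg0plus = (sr >= 0) & (tr >= 0)  # regions 1/2 (beyond s+t=det)

        # region 3: s=0, t=clamp(-e/c)
        m = reg3
        t2[m] = clamp01(-er[m] / np.maximum(cr[m], 1e-30))
        # region 5: t=0, s=clamp(-d/a)
        m = reg5
        s2[m] = clamp01(-dr[m] / np.maximum(ar[m], 1e-30))
        # region 4: corner
        m = reg4
        sm = clamp01(-dr[m] / np.maximum(ar[m], 1e-30))
        tm = clamp01(-er[m] / np.maximum(cr[m], 1e-30))
        use_s = (dr[m] < 0)
        s2[m] = np.where(use_s, sm, 0.0)
        t2[m] = np.where(use_s, 0.0, tm)
        # regions 1/2: on edge s+t=1
        m = reg0plus
        numer = (cr[m] + er[m]) - (br[m] + dr[m])
        denom = ar[m] - 2 * br[m] + cr[m]
        sm = clamp01(numer / np.maximum(denom, 1e-30))
        s2[m] = sm
        t2[m] = 1.0 - sm

        s_out[rem] = s2
        t_out[rem] = t2

    closest = B + s_out[:, None] * E0 + t_out[:, None] * E1
    dist = np.linalg.norm(closest - points, axis=1)
    return dist, closest


class MeshDistance:
    """Minimum-distance queries against one triangle mesh.

    Triangles are first subdivided to a bounded edge length so that
    k-nearest-centroid candidate pruning is reliable even for long skinny
    faces; the exact point-triangle distance is then evaluated on the
    candidates.
    """

    def __init__(self, mesh, max_edge: float | None = None):
        import trimesh.remesh

        v = np.asarray(mesh.vertices)
        f = np.asarray(mesh.faces)
        if max_edge is None:
            max_edge = float(np.linalg.norm(mesh.extents)) / 24.0
        v, f, _ = trimesh.remesh.subdivide_to_size(v, f, max_edge, return_index=True)
        self.vertices = v
        self.tris = v[f]
        self.centroids = self.tris.mean(axis=1)
        self.tree = cKDTree(self.centroids)
        self.radius = float(
            np.max(np.linalg.norm(self.tris - self.centroids[:, None, :], axis=2))
        )

    def query(self, points: np.ndarray, k: int = 8) -> tuple[np.ndarray, np.ndarray]:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        k = min(k, len(self.centroids))
        _, idx = self.tree.query(points, k=k)
        idx = np.atleast_2d(idx)
        rep = np.repeat(points, k, axis=0)
        dd, cc = point_triangle_distance(rep, self.tris[idx.reshape(-1)])
        dd = dd.reshape(n, k)
        cc = cc.reshape(n, k, 3)
        j = np.argmin(dd, axis=1)
        rows = np.arange(n)
        return dd[rows, j], cc[rows, j]


def points_in_mesh(points: np.ndarray, mesh, chunk: int = 512) -> np.ndarray:
    """Boolean containment of points in a watertight mesh.

    Vertical-ray parity count, vectorized over triangle chunks; no spatial
    index required.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tris = np.asarray(mesh.triangles)
    counts = np.zeros(len(points), dtype=np.int64)
    # irrational offsets break degenerate ray-through-edge alignments that
    # regular lattices of translated copies produce
    scale = float(np.max(np.ptp(tris.reshape(-1, 3), axis=0))) or 1.0
    px = points[:, 0] + 1e-7 * scale * 0.6180339887
    py = points[:, 1] + 1e-7 * scale * 0.4142135624
    pz = points[:, 2]
    for start in range(0, len(tris), chunk):
        t = tris[start : start + chunk]
        a, b, c = t[:, 0], t[:, 1], t[:, 2]
        v0 = (b - a)[:, :2]
        v1 = (c - a)[:, :2]
        det = v0[:, 0] * v1[:, 1] - v1[:, 0] * v0[:, 1]  # (m,)
        ok = np.abs(det) > 1e-14
        # pairwise (n, m)
        det_safe = np.where(ok, det, 1.0)
        dx = px[:, None] - a[None, :, 0]
        dy = py[:, None] - a[None, :, 1]
        w1 = (dx * v1[None, :, 1] - v1[None, :, 0] * dy) / det_safe[None, :]
        w2 = (v0[None, :, 0] * dy - dx * v0[None, :, 1]) / det_safe[None, :]
        inside = ok[None, :] & (w1 >= 0) & (w2 >= 0) & (w1 + w2 <= 1)
        z_at = (
            a[None, :, 2]
            + w1 * (b - a)[None, :, 2]
            + w2 * (c - a)[None, :, 2]
        )
        counts += np.sum(inside & (z_at > pz[:, None] + 1e-12), axis=1)
    return counts % 2 == 1


def mesh_min_distance(mesh_a, mesh_b) -> tuple[float, np.ndarray, np.ndarray]:
    """(distance, witness_on_a, witness_on_b) between two meshes.

    Symmetric vertex-to-surface query on subdivided meshes (exact for
    contacts at vertices or faces; residual edge-edge minima are bounded by
    the subdivided edge length).
    """
    qa = MeshDistance(mesh_a)
    qb = MeshDistance(mesh_b)
    da, pa = qb.query(qa.vertices)
    ia = int(np.argmin(da))
    db, pb = qa.query(qb.vertices)
    ib = int(np.argmin(db))
    if da[ia] <= db[ib]:
        return float(da[ia]), np.asarray(qa.vertices[ia]), pa[ia]
    return float(db[ib]), pb[ib], np.asarray(qb.vertices[ib])
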
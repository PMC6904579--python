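"""Brute-force geometric oracles, independent of the library's kernels.

Volume/centroid by vertical-column integration on a pixel grid (each
column's inside-intervals found from raw triangle crossings) and
silhouette area by pixel-center point-in-polygon counting.  Slow and
simple on purpose.
"""

from __future__ import annotations

import numpy as np
import shapely


def column_volume_centroid(mesh, pitch: float) -> tuple[float, np.ndarray]:
    """(volume, centroid) by z-column integration over an xy pixel grid."""
    tris = np.asarray(mesh.triangles)
    lo, hi = np.asarray(mesh.bounds)
    # offset breaks exact vertex/edge alignments
    xs = np.arange(lo[0] + 0.37 * pitch, hi[0], pitch)
    ys = np.arange(lo[1] + 0.41 * pitch, hi[1], pitch)
    nx, ny = len(xs), len(ys)
    crossings: dict[int, list[float]] = {}

    for t in tris:
        a, b, c = t
        v0 = (b - a)[:2]
        v1 = (c - a)[:2]
        det = v0[0] * v1[1] - v1[0] * v0[1]
        if abs(det) < 1e-14:
            continue
        i0 = np.searchsorted(xs, min(a[0], b[0], c[0]))
        i1 = np.searchsorted(xs, max(a[0], b[0], c[0]))
        j0 = np.searchsorted(ys, min(a[1], b[1], c[1]))
        j1 = np.searchsorted(ys, max(a[1], b[1], c[1]))
        if i0 == i1 or j0 == j1:
            continue
        gx, gy = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        dx = gx.ravel() - a[0]
        dy = gy.ravel() - a[1]
        w1 = (dx * v1[1] - v1[0] * dy) / det
        w2 = (v0[0] * dy - dx * v0[1]) / det
        inside = (w1 >= 0) & (w2 >= 0) & (w1 + w2 <= 1)
        if not inside.any():
            continue
        z = a[2] + w1 * (b - a)[2] + w2 * (c - a)[2]
        ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
        keys = (ii.ravel() * ny + jj.ravel())[inside]
        for k, zz in zip(keys, z[inside]):
            crossings.setdefault(int(k), []).append(float(zz))

    vol = 0.0
    mx = my = mz = 0.0
    for k, zl in crossings.items():
        if len(zl) < 2:
            continue
        zl = sorted(zl)
        i, j = divmod(k, ny)
        for q in range(0, len(zl) - 1, 2):
            seg = zl[q + 1] - zl[q]
            vol += seg
            mx += seg * xs[i]
            my += seg * ys[j]
            mz += seg * 0.5 * (zl[q] + zl[q + 1])
    a = pitch * pitch
    if vol == 0:
        return 0.0, np.zeros(3)
    return vol * a, np.array([mx, my, mz]) / vol


def raster_area(polygon, pitch: float) -> float:
    """Polygon area by pixel-center counting."""
    x0, y0, x1, y1 = polygon.bounds
    xs = np.arange(x0 + 0.37 * pitch, x1, pitch)
    ys = np.arange(y0 + 0.41 * pitch, y1, pitch)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    inside = shapely.contains_xy(polygon, gx.ravel(), gy.ravel())
    return float(inside.sum()) * pitch * pitch
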
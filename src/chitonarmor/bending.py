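"""Concave-bending kinematics of an armor panel.

The substrate midsurface is wrapped isometrically onto a cylinder of
prescribed curvature kappa whose axis is perpendicular to the loading
direction; the loading direction makes the orientation angle phi with the
hook axis (+Y), so phi = 0 bends along the hooks and phi = 90 across them.
Scales are rigid: each is carried by the rigid transform of the
midsurface frame at its site.  Positive kappa is the concave mode (scales
facing inward, tops converging — the side where scale-scale jamming
happens); negative kappa is the convex mode, where the scales separate.

Contacts are scale-to-scale minimum-distance events below a tolerance;
the contact graph records witness points and the lattice neighbor class
(hook-row / same-row / diagonal), and the onset curvature kappa* is the
smallest concave curvature with a non-empty interior contact graph,
located by bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .assembly import ArmorAssembly
from .errors import ParameterError

__all__ = ["BendState", "bend", "detect_contacts", "onset_curvature", "NO_INTERLOCKING"]

#: sentinel returned when no contact occurs within the curvature domain
NO_INTERLOCKING = float("inf")

_EDGE_CLASS = {"column": "hook_row", "row": "same_row", "diagonal": "diagonal"}


@dataclass
class BendState:
    assembly: ArmorAssembly
    phi_deg: float
    kappa: float  # 1/mm, positive = concave (scales inward)
    transforms: dict = field(repr=False, default_factory=dict)  # pid -> 4x4
    contact_graph: nx.Graph | None = None

    def scale_mesh(self, pid):
        m = self.assembly.scale_mesh(pid).copy()
        m.apply_transform(self.transforms[pid])
        return m

    def exposed_mesh(self, pid):
        m = self.assembly.exposed_mesh(pid).copy()
        m.apply_transform(self.transforms[pid])
        return m


def _panel_half_span(assembly: ArmorAssembly, e_b: np.ndarray) -> float:
    sites = np.array([p.site for p in assembly.placements])
    s = sites @ e_b[:2]
    return 0.5 * float(s.max() - s.min())


def bend(assembly: ArmorAssembly, phi_deg: float, kappa: float) -> BendState:
    """Wrap the panel onto a cylinder of curvature kappa at orientation phi.

    The midsurface (z = h1/2) is mapped isometrically; each rigid scale is
    carried by the frame of its own site.  kappa = 0 returns identity
    transforms.  Raises for curvatures that would wrap the sheet onto
    itself (|kappa| * half_span >= pi).
    """
    if not 0.0 <= phi_deg < 180.0:
        raise ParameterError("phi_deg must be in [0, 180)")
    phi = math.radians(phi_deg)
    e_b = np.array([math.sin(phi), math.cos(phi), 0.0])  # bending direction
    e_a = np.array([math.cos(phi), -math.sin(phi), 0.0])  # cylinder axis
    if kappa != 0.0:
        half = _panel_half_span(assembly, e_b)
        if abs(kappa) * half >= math.pi:
            raise ParameterError(
                f"over-curvature: |kappa|*half_span = {abs(kappa) * half:.3f} >= pi"
            )

    z_mid = 0.5 * assembly.h1
    transforms = {}
    for p in assembly.placements:
        if kappa == 0.0:
            transforms[p.pid] = np.eye(4)
            continue
        site3 = np.array([p.site[0], p.site[1], z_mid])
        s = float(site3 @ e_b)
        psi = kappa * s
        # wrapped midsurface point (arc length preserved along e_b)
        pos = (
            float(site3 @ e_a) * e_a
            + (math.sin(psi) / kappa) * e_b
            + np.array([0.0, 0.0, z_mid + (1.0 - math.cos(psi)) / kappa])
        )
        # rotate about the cylinder axis so the local frame follows the sheet
        rot = _axis_rotation(e_a, psi)
        t = np.eye(4)
        t[:3, :3] = rot
        t[:3, 3] = pos - rot @ site3
        transforms[p.pid] = t
    return BendState(assembly=assembly, phi_deg=phi_deg, kappa=kappa, transforms=transforms)


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    x, y, z = axis
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def detect_contacts(state: BendState, tolerance: float | None = None) -> nx.Graph:
    """Contact graph at this bend state.

    Edge (u, v) for every scale pair whose exposed surfaces (the parts
    above the substrate; embedded bases are separated by the matrix) come
    closer than the tolerance (default 0.05*d); edges carry witness points
    and the lattice neighbor class.  Non-neighbor pairs are screened by
    bounding-box distance first.
    """
    asm = state.assembly
    if tolerance is None:
        tolerance = 0.05 * asm.spec.spacing
    g = nx.Graph()
    for p in asm.placements:
        g.add_node(p.pid, interior=p.interior)

    tmpl_v, tmpl_f = asm.exposed_subdivided()
    tmpl_h = np.column_stack([tmpl_v, np.ones(len(tmpl_v))])
    verts = {}
    for p in asm.placements:
        total = state.transforms[p.pid] @ p.transform
        verts[p.pid] = (tmpl_h @ total.T)[:, :3]
    bounds = {pid: (v.min(axis=0), v.max(axis=0)) for pid, v in verts.items()}

    from scipy.spatial import cKDTree

    trees: dict = {}

    def tree_of(pid):
        if pid not in trees:
            tris = verts[pid][tmpl_f]
            trees[pid] = (cKDTree(tris.mean(axis=1)), tris)
        return trees[pid]

    def one_way(src, dst):
        from .geomutils import point_triangle_distance

        tree, tris = tree_of(dst)
        pts = verts[src]
        k = min(8, len(tris))
        _, idx = tree.query(pts, k=k)
        idx = np.atleast_2d(idx)
        rep = np.repeat(pts, k, axis=0)
        dd, cc = point_triangle_distance(rep, tris[idx.reshape(-1)])
        dd = dd.reshape(len(pts), k)
        cc = cc.reshape(len(pts), k, 3)
        j = np.argmin(dd, axis=1)
        rows = np.arange(len(pts))
        i = int(np.argmin(dd[rows, j]))
        return float(dd[i, j[i]]), pts[i], cc[i, j[i]]

    pids = list(verts)
    for a_i in range(len(pids)):
        for b_i in range(a_i + 1, len(pids)):
            u, v = pids[a_i], pids[b_i]
            if _aabb_gap(bounds[u], bounds[v]) > tolerance:
                continue
            d1, pu1, pv1 = one_way(u, v)
            d2, pv2, pu2 = one_way(v, u)
            dist, pu, pv = (d1, pu1, pv1) if d1 <= d2 else (d2, pu2, pv2)
            if dist < tolerance:
                kind = None
                if asm.lattice.has_edge(u, v):
                    kind = _EDGE_CLASS[asm.lattice.edges[u, v]["kind"]]
                g.add_edge(u, v, distance=dist, witness=(pu, pv), neighbor_class=kind)
    state.contact_graph = g
    return g


def _aabb_gap(b1, b2) -> float:
    lo = np.maximum(b1[0], b2[0])
    hi = np.minimum(b1[1], b2[1])
    gap = np.maximum(lo - hi, 0.0)
    return float(np.linalg.norm(gap))


def _interior_contacts(g: nx.Graph) -> list:
    return [
        (u, v)
        for u, v in g.edges
        if g.nodes[u].get("interior") or g.nodes[v].get("interior")
    ]


def onset_curvature(
    assembly: ArmorAssembly,
    phi_deg: float,
    tolerance: float | None = None,
    kappa_tol: float = 1e-4,
    kappa_max: float | None = None,
) -> tuple[float, str | None]:
    """Onset curvature of sustained interlocking at orientation phi.

    Kappa* is the lower edge of the contact regime that persists up to the
    curvature domain limit, located by bisection to kappa_tol (1/mm);
    transient riding contacts — a hook touching the back of the scale ahead
    and sliding over it as bending proceeds (the soft regime) — do not
    count as interlocking.  Returns (kappa*, neighbor_class of the closest
    first contact); (NO_INTERLOCKING, None) when the panel reaches the
    domain limit free of sustained contact.
    """
    phi = math.radians(phi_deg)
    e_b = np.array([math.sin(phi), math.cos(phi), 0.0])
    half = _panel_half_span(assembly, e_b)
    if kappa_max is None:
        # cap at a half-tube wrap: beyond it the panel's far ends curl
        # toward each other and register spurious end-to-end contacts
        kappa_max = 0.95 * (math.pi / 2.0) / max(half, 1e-9)

    def has_contact(k: float):
        g = detect_contacts(bend(assembly, phi_deg, k), tolerance)
        edges = _interior_contacts(g)
        return (len(edges) > 0), g, edges

    hit, g_hi, edges_hi = has_contact(kappa_max)
    if not hit:
        return NO_INTERLOCKING, None
    lo, hi = 0.0, kappa_max
    while hi - lo > kappa_tol:
        mid = 0.5 * (lo + hi)
        hit, g_mid, edges_mid = has_contact(mid)
        if hit:
            hi = mid
            g_hi, edges_hi = g_mid, edges_mid
        else:
            lo = mid
    first = min(edges_hi, key=lambda e: g_hi.edges[e]["distance"])
    return hi, g_hi.edges[first]["neighbor_class"]
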
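"""Armor assembly: tessellating scale instances into panels.

Scale bases form a diamond mosaic: two families of parallel (or fanning)
lines whose intersections carry one scale each.  Uniform panels use a
fixed inter-scale spacing d between neighboring base walls (the printed
prototypes use d/L = 5%); gradient panels derive per-site size factors
from the local cell area of two expanding line pencils; curved panels
carry the lattice onto a parametric host surface, orienting each scale
along the local normal and shrinking it where curvature is high.

The substrate is a slab of thickness h1 (the embedded height) with one
socket per scale, built constructively (2-D boolean of footprints plus
direct wall meshing) so no 3-D boolean engine is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import trimesh
from pydantic import BaseModel, ConfigDict
from shapely.geometry import Polygon, box as shapely_box
from shapely.ops import unary_union

from .curves import fillet_diamond
from .errors import GeometryError, ParameterError
from .geomutils import triangulate_polygon
from .loft import ScaleMesh, loft_scale
from .params import ScaleParameters
from .presets import DEFAULT_PRESET, load_preset

__all__ = [
    "FanSpec",
    "AssemblySpec",
    "Placement",
    "ArmorAssembly",
    "tile_uniform",
    "tile_gradient_fan",
    "tile_on_surface",
    "build_substrate",
    "PlaneHost",
    "CylinderHost",
    "SphereCapHost",
    "MeshHost",
]


class FanSpec(BaseModel):
    """One pencil of lines: line i passes through origin + i*spacing*n and
    points along axis rotated by i*divergence."""

    model_config = ConfigDict(extra="forbid")

    origin: tuple[float, float]
    axis_deg: float
    divergence_deg: float = 0.0
    spacing: float = 0.0
    count: int = 5

    def line(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        ang = math.radians(self.axis_deg + i * self.divergence_deg)
        d = np.array([math.cos(ang), math.sin(ang)])
        n0 = math.radians(self.axis_deg + 90.0)
        p = np.asarray(self.origin) + i * self.spacing * np.array(
            [math.cos(n0), math.sin(n0)]
        )
        return p, d


class AssemblySpec(BaseModel):
    """Input specification for an armor panel."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    pattern: str = "uniform"  # uniform | gradient_fan | on_surface
    preset: str = DEFAULT_PRESET
    params: Optional[ScaleParameters] = None  # overrides preset when given
    scale_length: float = 10.0  # L, mm (base footprint length)
    spacing: float = 0.5  # d, mm (nearest base-wall gap)
    embedded_height: Optional[float] = None  # h1, mm; None -> from the scale
    grid_rows: int = 5
    grid_cols: int = 5
    phi_deg: float = 0.0  # loading-axis angle from the hook direction
    n_sections: int = 24
    n_profile: int = 24
    fan_a: Optional[FanSpec] = None
    fan_b: Optional[FanSpec] = None
    fan_divergence_deg: float = 2.0  # used when fans are auto-derived
    host: object = None  # SurfaceHost for on_surface
    kappa_c: Optional[float] = None  # size-curvature rule constant (1/mm)

    def validate_spec(self) -> "AssemblySpec":
        if self.pattern not in ("uniform", "gradient_fan", "on_surface"):
            raise ParameterError(f"unknown pattern {self.pattern!r}")
        if self.scale_length <= 0:
            raise ParameterError("scale_length must be positive")
        if self.spacing < 0:
            raise ParameterError("spacing d must be non-negative")
        if self.spacing / self.scale_length >= 1.0:
            raise ParameterError("d/L must be < 1")
        if not 0.0 <= self.phi_deg < 180.0:
            raise ParameterError("phi_deg must be in [0, 180)")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ParameterError("grid must be at least 1x1")
        if self.embedded_height is not None and self.embedded_height <= 0:
            raise ParameterError("embedded_height must be positive")
        return self

    def scale_parameters(self) -> ScaleParameters:
        base = self.params if self.params is not None else load_preset(self.preset).params
        _, l_eff = base.footprint_extents()
        return base.scaled(self.scale_length / l_eff)


@dataclass
class Placement:
    pid: tuple[int, int]
    site: np.ndarray  # 2-D lattice coordinates (flat frame)
    transform: np.ndarray  # 4x4 rigid+scale transform applied to the template
    size_factor: float = 1.0
    cell_area: float = float("nan")
    interior: bool = False


@dataclass
class ArmorAssembly:
    spec: AssemblySpec
    scale_params: ScaleParameters
    template: ScaleMesh
    placements: list[Placement]
    lattice: nx.Graph
    footprint: Polygon
    base_polygon: np.ndarray  # scale base footprint contour (2-D, local)
    substrate_mesh: trimesh.Trimesh | None = None
    _meshes: dict = field(default_factory=dict, repr=False)

    @property
    def h1(self) -> float:
        if self.spec.embedded_height is not None:
            return self.spec.embedded_height
        return self.scale_params.h1

    def scale_mesh(self, pid) -> trimesh.Trimesh:
        """Transformed mesh of one placed scale (cached)."""
        if pid not in self._meshes:
            p = next(pl for pl in self.placements if pl.pid == pid)
            m = self.template.mesh.copy()
            m.apply_transform(p.transform)
            self._meshes[pid] = m
        return self._meshes[pid]

    def exposed_mesh(self, pid) -> trimesh.Trimesh:
        """The part of a placed scale above the substrate surface.

        The embedded base (below h1) is separated from its neighbors by the
        matrix, so scale-scale contact analysis acts on this submesh.
        """
        key = ("exposed", pid)
        if key not in self._meshes:
            if "exposed_template" not in self._meshes:
                t = self.template.mesh
                zc = t.triangles.mean(axis=1)[:, 2]
                keep = np.where(zc >= self.h1)[0]
                if keep.size == 0:
                    raise GeometryError("scales are entirely embedded in the substrate")
                self._meshes["exposed_template"] = t.submesh([keep], append=True)
            p = next(pl for pl in self.placements if pl.pid == pid)
            m = self._meshes["exposed_template"].copy()
            m.apply_transform(p.transform)
            self._meshes[key] = m
        return self._meshes[key]

    def interior_ids(self) -> list[tuple[int, int]]:
        return [p.pid for p in self.placements if p.interior]

    def exposed_subdivided(self) -> tuple[np.ndarray, np.ndarray]:
        """(vertices, faces) of the exposed template, subdivided for distance
        queries (bounded edge length makes centroid pruning reliable)."""
        key = "exposed_subdiv"
        if key not in self._meshes:
            import trimesh.remesh

            t = self.exposed_mesh(self.placements[0].pid)  # ensures template
            tmpl = self._meshes["exposed_template"]
            max_edge = float(np.linalg.norm(tmpl.extents)) / 24.0
            v, f, _ = trimesh.remesh.subdivide_to_size(
                tmpl.vertices, tmpl.faces, max_edge, return_index=True
            )
            self._meshes[key] = (v, f)
        return self._meshes[key]


# ------------------------------------------------------------------- lattice
def _lattice_vectors(width: float, length: float, d: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Diamond-lattice generators for a base diamond width x length (nominal
    vertex-to-vertex dimensions) with plan-view wall gap d.

    The base walls lie on the nominal diamond's edge lines (fillets only
    round the corners), so neighbor offsets proportional to (W/2, L/2) keep
    the walls parallel and the perpendicular in-plane gap exactly d.
    """
    r_e = (width * length / 2.0) / math.hypot(width, length)  # center-to-edge
    eta = d / (2.0 * r_e)
    a1 = (1.0 + eta) * np.array([width / 2.0, length / 2.0])
    a2 = (1.0 + eta) * np.array([width / 2.0, -length / 2.0])
    return a1, a2, eta


def _build_graph(sites: dict[tuple[int, int], np.ndarray]) -> nx.Graph:
    """Neighbor graph over lattice indices (i, j) = (a1-steps, a2-steps).

    Edge kinds: 'diagonal' (+-a1, +-a2), 'column' (a1 - a2: along the hook
    direction), 'row' (a1 + a2: along the width direction).
    """
    g = nx.Graph()
    for pid, xy in sites.items():
        g.add_node(pid, site=tuple(map(float, xy)))
    offsets = {
        (1, 0): "diagonal",
        (0, 1): "diagonal",
        (1, -1): "column",
        (1, 1): "row",
    }
    for (i, j) in sites:
        for (di, dj), kind in offsets.items():
            other = (i + di, j + dj)
            if other in sites:
                g.add_edge((i, j), other, kind=kind)
    for pid in g.nodes:
        i, j = pid
        diag = [(i + 1, j), (i - 1, j), (i, j + 1), (i, j - 1)]
        g.nodes[pid]["interior"] = all(n in g.nodes for n in diag)
    return g


def _block_sites(rows: int, cols: int, a1: np.ndarray, a2: np.ndarray):
    """Checkerboard block of rows x cols sites (rows along Y, cols along X)."""
    sites: dict[tuple[int, int], np.ndarray] = {}
    for r in range(rows):
        for c in range(cols):
            # lattice coordinates: moving one row up = a1 then a2 alternately
            i = (r + 1) // 2 + c
            j = c - r // 2
            sites[(i, j)] = i * a1 + j * a2
    return sites


# ------------------------------------------------------------------ builders
def _base_contour_2d(params: ScaleParameters, n: int = 48) -> np.ndarray:
    return fillet_diamond(
        params.width, params.length, params.fillet_front, params.fillet_side, n
    )


def _footprint(site_polys: list[Polygon], margin: float) -> Polygon:
    u = unary_union(site_polys)
    x0, y0, x1, y1 = u.bounds
    return shapely_box(x0 - margin, y0 - margin, x1 + margin, y1 + margin)


def _assemble(
    spec: AssemblySpec,
    sites: dict[tuple[int, int], np.ndarray],
    transforms: dict[tuple[int, int], np.ndarray],
    sizes: dict[tuple[int, int], float],
    areas: dict[tuple[int, int], float] | None = None,
) -> ArmorAssembly:
    params = spec.scale_parameters()
    template = loft_scale(params, spec.n_sections, spec.n_profile)
    graph = _build_graph(sites)
    base2d = _base_contour_2d(params)

    placements = []
    polys = []
    for pid, xy in sites.items():
        t = transforms[pid]
        placements.append(
            Placement(
                pid=pid,
                site=np.asarray(xy, dtype=float),
                transform=t,
                size_factor=sizes[pid],
                cell_area=(areas or {}).get(pid, float("nan")),
                interior=graph.nodes[pid]["interior"],
            )
        )
        poly2 = base2d * sizes[pid] + np.asarray(xy)[None, :]
        polys.append(Polygon(poly2))
        # the socket's top opening is shifted forward by the basal shear
        h_emb = spec.embedded_height if spec.embedded_height is not None else params.h1
        polys.append(Polygon(poly2 + np.array([0.0, params.shear * h_emb])[None, :]))
    footprint = _footprint(polys, margin=spec.spacing + 0.05 * spec.scale_length)
    return ArmorAssembly(
        spec=spec,
        scale_params=params,
        template=template,
        placements=placements,
        lattice=graph,
        footprint=footprint,
        base_polygon=base2d,
    )


def _translation(xy, z=0.0) -> np.ndarray:
    t = np.eye(4)
    t[0, 3], t[1, 3], t[2, 3] = xy[0], xy[1], z
    return t


def _scale_about(xy, f: float) -> np.ndarray:
    s = np.eye(4) * f
    s[3, 3] = 1.0
    return _translation(xy) @ s


def tile_uniform(spec: AssemblySpec) -> ArmorAssembly:
    """Uniform diamond-grid panel: identical scales, co-oriented hooks,
    nearest base-wall gap equal to the spacing d."""
    spec.validate_spec()
    if spec.pattern != "uniform":
        raise ParameterError("tile_uniform requires pattern='uniform'")
    params = spec.scale_parameters()
    a1, a2, _ = _lattice_vectors(params.width, params.length, spec.spacing)
    sites = _block_sites(spec.grid_rows, spec.grid_cols, a1, a2)
    transforms = {pid: _translation(xy) for pid, xy in sites.items()}
    sizes = {pid: 1.0 for pid in sites}
    return _assemble(spec, sites, transforms, sizes)


def _auto_fans(spec: AssemblySpec, a1, a2) -> tuple[FanSpec, FanSpec]:
    """Derive the two line pencils from the uniform lattice.

    Family A follows a1 (its lines separate consecutive j indices), family B
    follows a2.  Zero divergence reproduces the parallel-line (uniform)
    construction; positive divergence makes cells expand away from the
    pencil origins."""
    div = spec.fan_divergence_deg
    fans = []
    for av, other in ((a1, a2), (a2, a1)):
        ahat = av / np.linalg.norm(av)
        nhat = np.array([-ahat[1], ahat[0]])  # FanSpec offsets act along this
        h = float(other @ nhat)  # signed line spacing reproducing the lattice
        axis = math.degrees(math.atan2(ahat[1], ahat[0]))
        n_lines = (spec.grid_rows + spec.grid_cols) + 2
        if abs(div) < 1e-12:
            fans.append(
                FanSpec(origin=(0.0, 0.0), axis_deg=axis, divergence_deg=0.0, spacing=h, count=n_lines)
            )
        else:
            # pencil origin placed so line i's offset near the panel is
            # ~ i*h: dist*tan(i*div) ~ i*h  =>  dist = h / tan(div)
            dist = h / math.tan(math.radians(div))
            origin = -dist * ahat
            fans.append(
                FanSpec(
                    origin=(float(origin[0]), float(origin[1])),
                    axis_deg=axis,
                    divergence_deg=div,
                    spacing=0.0,
                    count=n_lines,
                )
            )
    return fans[0], fans[1]


def _line_intersection(p1, d1, p2, d2) -> np.ndarray:
    m = np.array([d1, -d2]).T
    det = np.linalg.det(m)
    if abs(det) < 1e-14:
        raise GeometryError("parallel pencil lines do not intersect")
    t = np.linalg.solve(m, p2 - p1)
    return p1 + t[0] * d1


def tile_gradient_fan(spec: AssemblySpec) -> ArmorAssembly:
    """Size-graded panel from two expanding line pencils.

    Scale centers sit on pencil-line intersections; each size factor is the
    square root of the local cell area over the largest cell area, so scale
    size decreases from the proximal (large-cell) to the distal rows."""
    spec.validate_spec()
    if spec.pattern != "gradient_fan":
        raise ParameterError("tile_gradient_fan requires pattern='gradient_fan'")
    params = spec.scale_parameters()
    a1, a2, _ = _lattice_vectors(params.width, params.length, spec.spacing)
    fan_a = spec.fan_a
    fan_b = spec.fan_b
    if fan_a is None or fan_b is None:
        auto_a, auto_b = _auto_fans(spec, a1, a2)
        fan_a = fan_a or auto_a
        fan_b = fan_b or auto_b
        spec.fan_a, spec.fan_b = fan_a, fan_b  # record the derived pencils
    if (
        fan_a.spacing == 0.0
        and fan_b.spacing == 0.0
        and np.allclose(fan_a.origin, fan_b.origin)
        and fan_a.divergence_deg == 0.0
        and fan_b.divergence_deg == 0.0
    ):
        raise ParameterError("degenerate fans: coincident origins with no divergence")

    # intersection sites; keep the same (i, j) indexing as the uniform block
    uniform_sites = _block_sites(spec.grid_rows, spec.grid_cols, a1, a2)
    sites = {}
    areas = {}
    for (i, j) in uniform_sites:
        pa, da = fan_a.line(j)  # A-lines separate a2 steps (index j)
        pb, db = fan_b.line(i)
        sites[(i, j)] = _line_intersection(pa, da, pb, db)
        corners = []
        for jj, ii in ((j - 0.5, i - 0.5), (j + 0.5, i - 0.5), (j + 0.5, i + 0.5), (j - 0.5, i + 0.5)):
            qa = fan_a.line(jj)
            qb = fan_b.line(ii)
            corners.append(_line_intersection(qa[0], qa[1], qb[0], qb[1]))
        areas[(i, j)] = float(Polygon(corners).area)
    amax = max(areas.values())
    sizes = {pid: math.sqrt(areas[pid] / amax) for pid in sites}
    transforms = {pid: _scale_about(sites[pid], sizes[pid]) for pid in sites}
    return _assemble(spec, sites, transforms, sizes, areas)


# ------------------------------------------------------------- surface hosts
class PlaneHost:
    """Flat host: identity mapping (tile_on_surface == tile_uniform)."""

    def point(self, u, v):
        return np.array([u, v, 0.0])

    def frame(self, u, v):
        return np.eye(3)  # columns: t_u, t_v, normal

    def kappa_max(self, u, v) -> float:
        return 0.0


class CylinderHost:
    """Cylinder of given radius, axis along Y; u is the arc coordinate."""

    def __init__(self, radius: float):
        if radius <= 0:
            raise ParameterError("cylinder radius must be positive")
        self.R = radius

    def point(self, u, v):
        a = u / self.R
        return np.array([self.R * math.sin(a), v, self.R * (1.0 - math.cos(a))])

    def frame(self, u, v):
        a = u / self.R
        tu = np.array([math.cos(a), 0.0, math.sin(a)])
        tv = np.array([0.0, 1.0, 0.0])
        n = np.array([-math.sin(a), 0.0, math.cos(a)])
        return np.column_stack([tu, tv, n])

    def kappa_max(self, u, v) -> float:
        return 1.0 / self.R

    def analytic_normal(self, u) -> np.ndarray:
        a = u / self.R
        return np.array([-math.sin(a), 0.0, math.cos(a)])


class SphereCapHost:
    """Spherical cap, geodesic-polar parameterization about the pole."""

    def __init__(self, radius: float):
        if radius <= 0:
            raise ParameterError("sphere radius must be positive")
        self.R = radius

    def point(self, u, v):
        r = math.hypot(u, v)
        if r < 1e-12:
            return np.array([0.0, 0.0, 0.0])
        a = r / self.R
        e = np.array([u / r, v / r])
        return np.array(
            [self.R * math.sin(a) * e[0], self.R * math.sin(a) * e[1], self.R * (1 - math.cos(a))]
        )

    def frame(self, u, v):
        r = math.hypot(u, v)
        if r < 1e-12:
            return np.eye(3)
        a = r / self.R
        e = np.array([u / r, v / r])
        perp = np.array([-e[1], e[0]])
        t_r = np.array([math.cos(a) * e[0], math.cos(a) * e[1], math.sin(a)])
        t_p = np.array([perp[0], perp[1], 0.0])
        n = np.array([-math.sin(a) * e[0], -math.sin(a) * e[1], math.cos(a)])
        # align columns with (u, v) directions
        tu = t_r * e[0] + t_p * (-e[1])
        tv = t_r * e[1] + t_p * e[0]
        return np.column_stack([tu / np.linalg.norm(tu), tv / np.linalg.norm(tv), n])

    def kappa_max(self, u, v) -> float:
        return 1.0 / self.R


class MeshHost:
    """Arbitrary oriented manifold mesh; sites found by vertical ray casting."""

    def __init__(self, mesh: trimesh.Trimesh):
        self.mesh = mesh
        zmax = float(mesh.bounds[1][2])
        self._z0 = zmax + 1.0

    def point_and_normal(self, u, v):
        origins = np.array([[u, v, self._z0]])
        dirs = np.array([[0.0, 0.0, -1.0]])
        loc, _, tri = self.mesh.ray.intersects_location(origins, dirs, multiple_hits=False)
        if len(loc) == 0:
            return None, None
        n = self.mesh.face_normals[tri[0]]
        if n[2] < 0:
            n = -n
        return loc[0], n

    def kappa_max(self, u, v) -> float:
        return 0.0  # per-face curvature not estimated for generic hosts


def tile_on_surface(spec: AssemblySpec) -> ArmorAssembly:
    """Carry the diamond lattice onto a host surface.

    Each scale's +Z follows the local surface normal and its hook (+Y)
    follows the v-parameter tangent; the size factor is min(1, kappa_c /
    kappa_max), shrinking scales where curvature is high."""
    spec.validate_spec()
    if spec.pattern != "on_surface":
        raise ParameterError("tile_on_surface requires pattern='on_surface'")
    host = spec.host or PlaneHost()
    params = spec.scale_parameters()
    a1, a2, _ = _lattice_vectors(params.width, params.length, spec.spacing)
    flat = _block_sites(spec.grid_rows, spec.grid_cols, a1, a2)
    kappa_c = spec.kappa_c if spec.kappa_c is not None else 0.5 / spec.scale_length

    sites = {}
    transforms = {}
    sizes = {}
    for pid, xy in flat.items():
        u, v = float(xy[0]), float(xy[1])
        if isinstance(host, MeshHost):
            pos, n = host.point_and_normal(u, v)
            if pos is None:
                continue
            tv = np.array([0.0, 1.0, 0.0])
            tv = tv - (tv @ n) * n
            tv /= np.linalg.norm(tv)
            tu = np.cross(tv, n)
            rot = np.column_stack([tu, tv, n])
            kap = host.kappa_max(u, v)
        else:
            pos = host.point(u, v)
            rot = host.frame(u, v)
            kap = host.kappa_max(u, v)
        f = 1.0 if kap <= 0 else min(1.0, kappa_c / kap)
        t = np.eye(4)
        t[:3, :3] = rot * f
        t[:3, 3] = pos
        sites[pid] = xy
        transforms[pid] = t
        sizes[pid] = f
    if not sites:
        raise ParameterError("host surface too small: no lattice site maps onto it")
    return _assemble(spec, sites, transforms, sizes)


# ----------------------------------------------------------------- substrate
def build_substrate(assembly: ArmorAssembly) -> trimesh.Trimesh:
    """Slab of thickness h1 with one socket per scale base.

    Sockets follow each base's shear (the prism leans toward the hook), so
    the slab volume equals footprint_area*h1 minus the embedded base
    volumes.  For curved hosts the flat slab-with-sockets mesh is wrapped
    through the host mapping along local normals.
    """
    spec = assembly.spec
    h1 = assembly.h1
    params = assembly.scale_params
    shear = params.shear  # forward offset per unit height
    base2d = assembly.base_polygon

    rect = assembly.footprint
    bottom_holes = []
    top_holes = []
    rings_b = []
    rings_t = []
    for p in assembly.placements:
        f = p.size_factor
        b = base2d * f + p.site[None, :]
        t = b + np.array([0.0, shear * h1])[None, :]
        if not rect.contains(Polygon(b)) or not rect.contains(Polygon(t)):
            raise GeometryError(f"socket {p.pid} exceeds the substrate footprint")
        bottom_holes.append(Polygon(b))
        top_holes.append(Polygon(t))
        rings_b.append(b)
        rings_t.append(t)

    def cap(z: float, holes: list[Polygon], up: bool) -> trimesh.Trimesh:
        poly = rect.difference(unary_union(holes)) if holes else rect
        if poly.geom_type == "MultiPolygon":
            raise GeometryError("substrate footprint split by sockets")
        v2, f2 = triangulate_polygon(poly)
        v3 = np.column_stack([v2, np.full(len(v2), z)])
        faces = f2 if up else f2[:, ::-1]
        return trimesh.Trimesh(v3, faces, process=False)

    parts = [cap(0.0, bottom_holes, up=False), cap(h1, top_holes, up=True)]

    # outer walls
    x0, y0, x1, y1 = rect.bounds
    rb = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
    parts.append(_wall_strip(rb, rb, 0.0, h1, outward=True))
    # socket walls (normals toward the socket interior = out of the solid)
    for b, t in zip(rings_b, rings_t):
        parts.append(_wall_strip(b, t, 0.0, h1, outward=False))

    mesh = trimesh.util.concatenate(parts)
    mesh.merge_vertices(merge_tex=True, merge_norm=True)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise GeometryError("substrate mesh failed to close")

    host = spec.host
    if spec.pattern == "on_surface" and host is not None and not isinstance(host, (PlaneHost,)):
        mesh = _wrap_onto_host(mesh, host)
    assembly.substrate_mesh = mesh
    return mesh


def _wall_strip(bottom2d: np.ndarray, top2d: np.ndarray, z0: float, z1: float, outward: bool):
    n = len(bottom2d)
    vb = np.column_stack([bottom2d, np.full(n, z0)])
    vt = np.column_stack([top2d, np.full(n, z1)])
    verts = np.vstack([vb, vt])
    faces = []
    for k in range(n):
        k2 = (k + 1) % n
        if outward:
            faces.append([k, k2, n + k2])
            faces.append([k, n + k2, n + k])
        else:
            faces.append([k, n + k2, k2])
            faces.append([k, n + k, n + k2])
    return trimesh.Trimesh(verts, np.array(faces), process=False)


def _wrap_onto_host(mesh: trimesh.Trimesh, host) -> trimesh.Trimesh:
    wrapped = mesh.copy()
    v = wrapped.vertices
    out = np.empty_like(v)
    for i, (u, vv, z) in enumerate(v):
        if isinstance(host, MeshHost):
            pos, n = host.point_and_normal(u, vv)
            if pos is None:
                raise GeometryError("substrate extends beyond the host surface")
        else:
            pos = host.point(u, vv)
            n = host.frame(u, vv)[:, 2]
        out[i] = pos + z * n
    wrapped.vertices = out
    return wrapped
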
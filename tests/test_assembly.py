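import math

import numpy as np
import pytest
from shapely.geometry import Polygon
from shapely.ops import unary_union

import chitonarmor as ca
from chitonarmor.geomutils import points_in_mesh
from chitonarmor.morphometrics import project_contours


def base_poly(asm, pid):
    p = next(pl for pl in asm.placements if pl.pid == pid)
    return Polygon(asm.base_polygon * p.size_factor + p.site[None, :])


class TestUniform:
    def test_diagonal_wall_gap_equals_d(self, rc_assembly):
        """Brute-force polygon distance between every adjacent base pair."""
        g = rc_assembly.lattice
        d = rc_assembly.spec.spacing
        for u, v in g.edges:
            gap = base_poly(rc_assembly, u).distance(base_poly(rc_assembly, v))
            if g.edges[u, v]["kind"] == "diagonal":
                assert abs(gap - d) < 1e-6
            else:
                assert gap > d - 1e-9  # diagonal neighbors are the closest

    def test_gap_over_length_is_five_percent(self, rc_assembly):
        g = rc_assembly.lattice
        gaps = [
            base_poly(rc_assembly, u).distance(base_poly(rc_assembly, v))
            for u, v in g.edges
            if g.edges[u, v]["kind"] == "diagonal"
        ]
        assert math.isclose(min(gaps) / rc_assembly.spec.scale_length, 0.05, rel_tol=1e-6)

    def test_single_cell_grid(self):
        spec = ca.AssemblySpec(
            pattern="uniform", grid_rows=1, grid_cols=1, n_sections=16, n_profile=16
        )
        asm = ca.tile_uniform(spec)
        assert len(asm.placements) == 1
        assert np.allclose(asm.placements[0].site, 0.0)

    def test_interior_nodes_have_four_diagonal_neighbors(self, rc_assembly):
        g = rc_assembly.lattice
        for pid in rc_assembly.interior_ids():
            kinds = [g.edges[pid, n]["kind"] for n in g.neighbors(pid)]
            assert kinds.count("diagonal") == 4

    def test_reference_state_disjoint(self, rc_assembly):
        """No two placed scales interpenetrate in the flat reference."""
        g = rc_assembly.lattice
        for u, v in g.edges:
            mu, mv = rc_assembly.scale_mesh(u), rc_assembly.scale_mesh(v)
            assert not points_in_mesh(mu.vertices, mv).any()
            assert not points_in_mesh(mv.vertices, mu).any()

    def test_dorsal_coverage_of_interior_cells(self):
        """The plan-view union of scales covers >= 99% of the interior cells."""
        spec = ca.AssemblySpec(
            pattern="uniform",
            preset="rhyssoplax_canariensis",
            scale_length=10.0,
            spacing=0.5,
            grid_rows=5,
            grid_cols=5,
            n_sections=24,
            n_profile=24,
        )
        asm = ca.tile_uniform(spec)
        _, bottom = project_contours(asm.template)
        union = unary_union(
            [
                Polygon(np.asarray(bottom.exterior.coords) + p.site[None, :])
                for p in asm.placements
            ]
        )
        a1 = np.array(asm.lattice.nodes[(1, 0)]["site"]) - np.array(
            asm.lattice.nodes[(0, 0)]["site"]
        )
        a2 = np.array(asm.lattice.nodes[(1, 1)]["site"]) - np.array(
            asm.lattice.nodes[(1, 0)]["site"]
        )
        cells = []
        for pid in asm.interior_ids():
            s = np.array(asm.lattice.nodes[pid]["site"])
            cells.append(
                Polygon(
                    [s + 0.5 * (a1 + a2), s + 0.5 * (a1 - a2), s - 0.5 * (a1 + a2), s - 0.5 * (a1 - a2)]
                )
            )
        interior = unary_union(cells)
        assert union.intersection(interior).area / interior.area >= 0.99

    def test_spec_validation_errors(self):
        with pytest.raises(ca.ParameterError):
            ca.AssemblySpec(pattern="hexagonal").validate_spec()
        with pytest.raises(ca.ParameterError):
            ca.AssemblySpec(spacing=-1.0).validate_spec()
        with pytest.raises(ca.ParameterError):
            ca.AssemblySpec(spacing=11.0, scale_length=10.0).validate_spec()


class TestGradientFan:
    def test_zero_divergence_reduces_to_uniform(self):
        kw = dict(scale_length=10.0, spacing=0.5, grid_rows=3, grid_cols=3, n_sections=16, n_profile=16)
        asm_u = ca.tile_uniform(ca.AssemblySpec(pattern="uniform", **kw))
        asm_f = ca.tile_gradient_fan(
            ca.AssemblySpec(pattern="gradient_fan", fan_divergence_deg=0.0, **kw)
        )
        tu = {p.pid: p.transform for p in asm_u.placements}
        tf = {p.pid: p.transform for p in asm_f.placements}
        assert set(tu) == set(tf)
        for pid in tu:
            assert np.allclose(tu[pid], tf[pid], atol=1e-9)

    def test_sizes_decrease_along_columns(self):
        asm = ca.tile_gradient_fan(
            ca.AssemblySpec(
                pattern="gradient_fan",
                grid_rows=5,
                grid_cols=3,
                fan_divergence_deg=3.0,
                n_sections=16,
                n_profile=16,
            )
        )
        cols = {}
        for p in asm.placements:
            i, j = p.pid
            cols.setdefault(i + j, []).append((i - j, p.size_factor))
        for _, col in cols.items():
            sizes = [s for _, s in sorted(col)]
            assert all(a > b for a, b in zip(sizes, sizes[1:]))

    def test_cell_areas_match_polygon_clipping_oracle(self):
        """Cell areas from corner intersections equal brute-force clipping of
        the two line-pencil strips."""
        from shapely.geometry import box as shapely_box

        spec = ca.AssemblySpec(
            pattern="gradient_fan",
            grid_rows=3,
            grid_cols=3,
            fan_divergence_deg=4.0,
            n_sections=16,
            n_profile=16,
        )
        asm = ca.tile_gradient_fan(spec)
        fan_a, fan_b = spec.fan_a, spec.fan_b
        big = 1e4
        world = shapely_box(-big, -big, big, big)

        def halfplane_strip(fan, i, site):
            strip = world
            for p0, d0 in (fan.line(i - 0.5), fan.line(i + 0.5)):
                n = np.array([-d0[1], d0[0]])
                if float((site - p0) @ n) < 0:
                    n = -n  # orient the half plane toward the cell's site
                t = np.array([d0[0], d0[1]])
                corners = [
                    p0 - big * t,
                    p0 + big * t,
                    p0 + big * t + big * n,
                    p0 - big * t + big * n,
                ]
                strip = strip.intersection(Polygon(corners))
            return strip

        for p in asm.placements:
            i, j = p.pid
            cell = halfplane_strip(fan_a, j, p.site).intersection(
                halfplane_strip(fan_b, i, p.site)
            )
            assert abs(cell.area / p.cell_area - 1.0) < 1e-9

    def test_degenerate_fans_rejected(self):
        fan = ca.FanSpec(origin=(0.0, 0.0), axis_deg=30.0, divergence_deg=0.0, spacing=0.0)
        spec = ca.AssemblySpec(pattern="gradient_fan", fan_a=fan, fan_b=fan)
        with pytest.raises(ca.ParameterError, match="degenerate fans"):
            ca.tile_gradient_fan(spec)


class TestOnSurface:
    kw = dict(scale_length=10.0, spacing=0.5, grid_rows=3, grid_cols=3, n_sections=16, n_profile=16)

    def test_plane_host_equals_uniform(self):
        asm_u = ca.tile_uniform(ca.AssemblySpec(pattern="uniform", **self.kw))
        asm_p = ca.tile_on_surface(
            ca.AssemblySpec(pattern="on_surface", host=ca.PlaneHost(), **self.kw)
        )
        tu = {p.pid: p.transform for p in asm_u.placements}
        tp = {p.pid: p.transform for p in asm_p.placements}
        for pid in tu:
            assert np.allclose(tu[pid], tp[pid], atol=1e-9)

    def test_cylinder_normals(self):
        host = ca.CylinderHost(60.0)
        asm = ca.tile_on_surface(ca.AssemblySpec(pattern="on_surface", host=host, **self.kw))
        for p in asm.placements:
            z = p.transform[:3, 2] / np.linalg.norm(p.transform[:3, 2])
            n = host.analytic_normal(p.site[0])
            ang = math.degrees(math.acos(np.clip(float(z @ n), -1, 1)))
            assert ang < 0.1

    def test_sphere_cap_size_monotone_in_curvature(self):
        sizes = []
        for radius in (40.0, 25.0, 12.0):
            asm = ca.tile_on_surface(
                ca.AssemblySpec(pattern="on_surface", host=ca.SphereCapHost(radius), **self.kw)
            )
            sizes.append(asm.placements[0].size_factor)
        assert sizes[0] >= sizes[1] >= sizes[2]
        assert sizes[2] < 1.0


class TestSubstrate:
    def test_thickness_and_watertight(self, rc_assembly):
        sub = ca.build_substrate(rc_assembly)
        assert sub.is_watertight
        thick = sub.bounds[1][2] - sub.bounds[0][2]
        assert math.isclose(thick, 4.1, abs_tol=1e-9)

    def test_volume_is_slab_minus_bases(self, rc_assembly):
        """Against the analytic slab volume and a voxel-column oracle."""
        from oracles import column_volume_centroid

        sub = rc_assembly.substrate_mesh or ca.build_substrate(rc_assembly)
        x0, y0, x1, y1 = rc_assembly.footprint.bounds
        base_area = Polygon(rc_assembly.base_polygon).area
        expected = (x1 - x0) * (y1 - y0) * 4.1 - len(rc_assembly.placements) * base_area * 4.1
        assert abs(sub.volume / expected - 1.0) < 1e-6
        vol, _ = column_volume_centroid(sub, pitch=0.25)
        assert abs(vol / expected - 1.0) < 0.01

    def test_empty_placement_slab(self):
        spec = ca.AssemblySpec(pattern="uniform", grid_rows=1, grid_cols=1, n_sections=16, n_profile=16)
        asm = ca.tile_uniform(spec)
        asm.placements = []
        sub = ca.build_substrate(asm)
        assert sub.is_watertight
        x0, y0, x1, y1 = asm.footprint.bounds
        assert math.isclose(sub.volume, (x1 - x0) * (y1 - y0) * asm.h1, rel_tol=1e-9)
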
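import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon, box

import chitonarmor as ca
from chitonarmor.geomutils import (
    mesh_min_distance,
    point_triangle_distance,
    points_in_mesh,
    triangulate_polygon,
)


def tri_area_sum(v2, f2):
    s = 0.0
    for f in f2:
        a, b, c = v2[f]
        s += ((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])) / 2
    return s


class TestTriangulation:
    @pytest.mark.parametrize(
        "poly",
        [
            box(0, 0, 10, 10),
            box(0, 0, 10, 10).difference(box(4, 4, 6, 6)),
            box(0, 0, 10, 10).difference(Polygon([(5, 3), (7, 5), (5, 7), (3, 5)])),
            box(0, 0, 10, 10).difference(box(1, 1, 3, 3)).difference(box(6, 6, 8, 8)),
        ],
    )
    def test_area_preserved(self, poly):
        v2, f2 = triangulate_polygon(poly)
        assert abs(tri_area_sum(v2, f2) - poly.area) < 1e-9
        # all triangles positively oriented (no overlapping garbage)
        for f in f2:
            a, b, c = v2[f]
            assert (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]) > 0

    def test_many_diamond_holes(self, rc_assembly):
        """The substrate cap case: a rectangle minus nine filleted diamonds."""
        from shapely.ops import unary_union

        holes = [
            Polygon(rc_assembly.base_polygon + np.array(p.site)[None, :])
            for p in rc_assembly.placements
        ]
        poly = rc_assembly.footprint.difference(unary_union(holes))
        v2, f2 = triangulate_polygon(poly)
        assert abs(tri_area_sum(v2, f2) - poly.area) < 1e-6

    def test_empty_polygon_rejected(self):
        with pytest.raises(ca.GeometryError):
            triangulate_polygon(Polygon())


class TestDistances:
    def test_point_triangle_regions(self):
        tri = np.array([[[0, 0, 0], [1, 0, 0], [0, 1, 0]]], dtype=float)
        cases = [
            ([0.25, 0.25, 1.0], 1.0),  # above interior
            ([-1.0, -1.0, 0.0], np.sqrt(2)),  # corner region
            ([0.5, -2.0, 0.0], 2.0),  # edge region
            ([2.0, 2.0, 0.0], np.sqrt(2 * 1.5**2)),  # beyond hypotenuse
        ]
        for p, expect in cases:
            d, _ = point_triangle_distance(np.array([p]), tri)
            assert abs(d[0] - expect) < 1e-12

    def test_two_cubes_known_gap(self):
        a = trimesh.creation.box((1, 1, 1))
        b = trimesh.creation.box((1, 1, 1))
        b.apply_translation([2.0, 0, 0])  # face-to-face gap of 1
        d, pa, pb = mesh_min_distance(a, b)
        assert abs(d - 1.0) < 1e-9
        assert abs(pa[0] - 0.5) < 1e-9 and abs(pb[0] - 1.5) < 1e-9

    def test_contact_graph_tolerance_threshold(self):
        """Two unit cubes 1 mm apart: no edge below tolerance 0.1, one edge
        at tolerance 1.01."""
        a = trimesh.creation.box((1, 1, 1))
        b = trimesh.creation.box((1, 1, 1))
        b.apply_translation([2.0, 0, 0])
        d, _, _ = mesh_min_distance(a, b)
        assert not d < 0.1
        assert d < 1.01

    def test_containment_parity(self):
        m = trimesh.creation.box((2, 2, 2))
        pts = np.array([[0, 0, 0], [0.9, 0.9, 0.9], [1.5, 0, 0], [0, 0, 1.1]])
        assert list(points_in_mesh(pts, m)) == [True, True, False, False]


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    dx=st.floats(1.05, 3.0),
    dz=st.floats(-0.4, 0.4),
)
def test_box_gap_property(dx, dz):
    """Axis-separated unit boxes: minimum distance equals the face gap."""
    a = trimesh.creation.box((1, 1, 1))
    b = trimesh.creation.box((1, 1, 1))
    b.apply_translation([dx, 0.0, dz])
    d, _, _ = mesh_min_distance(a, b)
    expect = dx - 1.0 if abs(dz) <= 1.0 else np.hypot(dx - 1.0, abs(dz) - 1.0)
    assert abs(d - expect) < 1e-9
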
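import math

import numpy as np
import pytest
from shapely.geometry import Polygon

import chitonarmor as ca
from chitonarmor.curves import build_principal_curves, extract_spine
from chitonarmor.params import ALL_MARKERS


@pytest.fixture(scope="module")
def rc_curves(rc_preset):
    return build_principal_curves(rc_preset.params)


def test_twenty_labelled_markers(rc_curves):
    assert set(rc_curves.markers) == set(ALL_MARKERS)
    assert len(rc_curves.markers) == 20
    yz = [k for k in rc_curves.markers if k.startswith("yz_")]
    assert len(yz) == 7


def test_base_contour_closed_simple(rc_curves):
    poly = Polygon(rc_curves.base_contour)
    assert poly.is_valid
    w, l = rc_curves.params.footprint_extents()
    x0, y0, x1, y1 = poly.bounds
    assert math.isclose(x1 - x0, w, rel_tol=1e-6)
    assert math.isclose(y1 - y0, l, rel_tol=1e-6)


def test_yz_outline_simple_and_anchored(rc_curves):
    poly = Polygon(rc_curves.yz_outline)
    assert poly.is_valid
    # open curve endpoints on the base plane, inside the footprint
    _, l = rc_curves.params.footprint_extents()
    for end in (rc_curves.yz_curve[0], rc_curves.yz_curve[-1]):
        assert abs(end[1]) < 1e-9
        assert abs(end[0]) <= l / 2 + 1e-9


def test_clamped_tangents_match_angle_parameters(rc_curves):
    """Basal edge leaves the base at beta; the outer surface arrives at the
    tip along the hook axis (angle alpha+beta-180)."""
    p = rc_curves.params
    post = rc_curves.segments["posterior_straight"]
    d = post[-1] - post[0]
    assert math.isclose(math.degrees(math.atan2(d[1], d[0])), p.beta_deg, abs_tol=1e-6)
    outer = rc_curves.segments["outer"]
    d = outer[-1] - outer[-2]
    assert math.isclose(
        math.degrees(math.atan2(d[1], d[0])), p.tip_tangent_deg, abs_tol=1.0
    )


def test_nonoverlap_parameters_rejected():
    with pytest.raises(ca.ParameterError, match="non-overlapping"):
        build_principal_curves(
            ca.ScaleParameters(
                width=0.4,
                length=1.0,
                fillet_front=0.02,
                fillet_side=0.02,
                beta_deg=70.0,
                h1=0.2,
                height=0.5,
                alpha_deg=130.0,
                hook_reach=0.05,
                tip_height_frac=0.8,
                back_inflection_frac=0.5,
                apex_shift_frac=0.5,
                under_bulge_frac=0.1,
                back_bulge_frac=0.1,
                shoulder_width_frac=0.8,
                shoulder_height_frac=0.4,
                crown_roundness=1.0,
            )
        )


def test_double_curve_parameters_make_s_shaped_outline():
    """The L. mertensii-class preset has two sustained curvature regimes on
    its dorsal boundary (two inflection points of the flap)."""
    pr = ca.load_preset("lepidozona_mertensii")
    c = build_principal_curves(pr.params)
    dorsal = np.vstack([c.segments["crown"], c.segments["outer"][1:]])
    seg = np.diff(dorsal, axis=0)
    theta = np.unwrap(np.arctan2(seg[:, 1], seg[:, 0]))
    dth = np.degrees(np.diff(theta))
    pos, neg = dth[dth > 0].sum(), -dth[dth < 0].sum()
    assert min(pos, neg) > 30.0  # substantial turning in both senses


class TestSpine:
    def test_prism_spine_is_vertical_segment(self):
        p = ca.ScaleParameters.prism(1.0, 1.0, 2.0)
        sp = extract_spine(build_principal_curves(p))
        assert np.allclose(sp[:, 0], 0.0, atol=1e-9)
        assert math.isclose(sp[-1, 1] - sp[0, 1], 2.0, rel_tol=1e-9)

    def test_spine_longer_than_height(self, rc_curves):
        sp = extract_spine(rc_curves)
        arc = float(np.sum(np.linalg.norm(np.diff(sp, axis=0), axis=1)))
        assert arc > rc_curves.params.height

    def test_spine_endpoints_match_medial_endpoints(self, rc_curves):
        """Base-plane midpoint to hook tip, against densely resampled
        boundary curves."""
        sp = extract_spine(rc_curves, n=800)
        start_expect = 0.5 * (rc_curves.anterior[0] + rc_curves.posterior[0])
        tip_expect = rc_curves.markers["yz_tip"][1:]
        assert np.linalg.norm(sp[0] - start_expect) < 1e-6
        assert np.linalg.norm(sp[-1] - tip_expect) < 1e-6
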
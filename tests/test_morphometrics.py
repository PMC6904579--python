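import math

import numpy as np
import pytest
import trimesh

import chitonarmor as ca
from oracles import column_volume_centroid, raster_area


def test_unit_cube_descriptors():
    box = ca.generate_fixtures("box", width=1.0, length=1.0, height=1.0)[0]
    r = ca.measure(box)
    assert math.isclose(r.W, 1.0, rel_tol=1e-9)
    assert math.isclose(r.L, 1.0, rel_tol=1e-9)
    assert math.isclose(r.H, 1.0, rel_tol=1e-9)
    assert math.isclose(r.V, 1.0, rel_tol=1e-9)
    assert math.isclose(r.A_total, 1.0, rel_tol=1e-9)
    assert np.allclose(r.centroid, [0.0, 0.0, 0.5], atol=1e-9)
    assert "degenerate" in r.flags
    assert r.alpha_deg == 180.0


def test_box_projection_contours():
    box = ca.generate_fixtures("box", width=0.8, length=1.2, height=0.6)[0]
    transverse, bottom = ca.project_contours(box)
    assert math.isclose(transverse.area, 1.2 * 0.6, rel_tol=1e-9)
    assert math.isclose(bottom.area, 0.8 * 1.2, rel_tol=1e-9)


def test_inclined_prism_recovers_inclination():
    prism = ca.generate_fixtures("inclined_prism", beta_deg=30.0)[0]
    r = ca.measure(prism)
    assert abs(r.beta_deg - 30.0) < 0.5
    # sheared silhouette is a parallelogram: area preserved
    transverse, _ = ca.project_contours(prism)
    assert math.isclose(transverse.area, 1.0, rel_tol=1e-6)


def test_roundtrip_parameter_recovery(preset_records):
    """Measuring a generated mesh recovers its generating parameters."""
    for key, (pr, rec) in preset_records.items():
        p = pr.params
        assert abs(rec.alpha_deg - p.alpha_deg) <= 2.0, key
        assert abs(rec.beta_deg - p.beta_deg) <= 2.0, key
        assert abs(rec.h1 / p.h1 - 1.0) <= 0.02, key
        assert abs(rec.H / p.height - 1.0) <= 0.02, key
        w, l = p.footprint_extents()
        assert abs(rec.W / w - 1.0) <= 0.02, key
        assert abs(rec.L / l - 1.0) <= 0.02, key


def test_scale_equivariance(rc_preset, rc_record):
    s = 2.0
    rec2 = ca.measure(ca.loft_scale(rc_preset.params.scaled(s), 64, 64))
    r1 = rc_record
    assert math.isclose(rec2.L, s * r1.L, rel_tol=1e-3)
    assert math.isclose(rec2.H, s * r1.H, rel_tol=1e-3)
    assert math.isclose(rec2.A_total, s**2 * r1.A_total, rel_tol=1e-3)
    assert math.isclose(rec2.V, s**3 * r1.V, rel_tol=1e-3)
    assert abs(rec2.alpha_deg - r1.alpha_deg) < 0.2
    assert abs(rec2.beta_deg - r1.beta_deg) < 0.2
    assert math.isclose(rec2.overlap_ratio, r1.overlap_ratio, rel_tol=1e-3)


def test_additivity_identities_exact(rc_record):
    assert rc_record.H == rc_record.h1 + rc_record.h2
    assert rc_record.A_total == rc_record.A1 + rc_record.A2


def test_contour_areas_against_raster_oracle(rc_mesh):
    transverse, bottom = ca.project_contours(rc_mesh)
    for poly in (transverse, bottom):
        assert abs(raster_area(poly, 0.005) / poly.area - 1.0) < 0.005


def test_volume_centroid_against_column_oracle(rc_mesh, rc_record):
    vol, cen = column_volume_centroid(rc_mesh.mesh, pitch=0.004)
    assert abs(vol / rc_record.V - 1.0) < 0.01
    assert np.linalg.norm(cen - rc_record.centroid) < 0.010  # 10 um


class TestBasalCenterOfMass:
    def test_all_species_presets_basal(self, preset_records):
        for key, (pr, rec) in preset_records.items():
            assert ca.basal_com_check(rec), key

    def test_top_heavy_mushroom_fails(self):
        mush = ca.generate_fixtures("mushroom")[0]
        r = ca.measure(mush)
        assert not ca.basal_com_check(r)

    def test_decision_matches_voxel_centroid(self, rc_mesh, rc_record):
        _, cen = column_volume_centroid(rc_mesh.mesh, pitch=0.004)
        assert (cen[2] < rc_record.h1) == ca.basal_com_check(rc_record)


def test_curvature_class_flags(preset_records):
    """Only the doubly-curved species carries the multi-inflection flag."""
    for key, (pr, rec) in preset_records.items():
        flagged = "multi-inflection" in rec.flags
        assert flagged == (key == "lepidozona_mertensii"), key


def test_auto_pose_recovers_canonical_frame(rc_preset, rc_record):
    m = ca.loft_scale(rc_preset.params, 48, 48).mesh.copy()
    T = trimesh.transformations.rotation_matrix(np.pi / 2, [0, 0, 1])
    m.apply_transform(T)
    m.apply_translation([1.0, -2.0, 0.3])
    r = ca.measure(m, pose="auto")
    assert abs(r.alpha_deg - rc_record.alpha_deg) < 1.0
    assert abs(r.beta_deg - rc_record.beta_deg) < 0.5
    assert abs(r.W / rc_record.W - 1.0) < 0.02  # PCA re-posing residual


def test_measure_rejects_open_meshes():
    box = ca.generate_fixtures("box")[0].mesh.copy()
    box.update_faces(np.arange(len(box.faces) - 2))  # drop faces -> open
    with pytest.raises(ca.GeometryError):
        ca.measure(box)
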
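import math

import numpy as np
import pytest

import chitonarmor as ca
from chitonarmor.bending import NO_INTERLOCKING


@pytest.fixture(scope="module")
def onset90(prototype_assembly):
    k, cls = ca.onset_curvature(prototype_assembly, 90.0)
    assert k != NO_INTERLOCKING
    return k, cls


def test_zero_curvature_is_identity(prototype_assembly):
    st = ca.bend(prototype_assembly, 0.0, 0.0)
    assert all(np.allclose(t, np.eye(4)) for t in st.transforms.values())


def test_relative_rotation_matches_cylinder_map(prototype_assembly):
    """Adjacent scales along the bend direction rotate relative to each
    other by exactly kappa * site spacing (closed-form cylinder map)."""
    k = 0.002
    st = ca.bend(prototype_assembly, 0.0, k)
    g = prototype_assembly.lattice
    u, v = next((u, v) for u, v in g.edges if g.edges[u, v]["kind"] == "column")
    rel = st.transforms[u][:3, :3].T @ st.transforms[v][:3, :3]
    ang = math.acos(np.clip((np.trace(rel) - 1) / 2, -1, 1))
    pitch = abs(g.nodes[u]["site"][1] - g.nodes[v]["site"][1])
    assert abs(ang / (k * pitch) - 1.0) < 1e-9


def test_convex_bending_is_contact_free(prototype_assembly):
    for kappa in (-0.02, -0.08):
        g = ca.detect_contacts(ca.bend(prototype_assembly, 90.0, kappa))
        assert g.number_of_edges() == 0


def test_over_curvature_raises(prototype_assembly):
    with pytest.raises(ca.ParameterError, match="over-curvature"):
        ca.bend(prototype_assembly, 90.0, 1.0)


def test_phi_domain(prototype_assembly):
    with pytest.raises(ca.ParameterError):
        ca.bend(prototype_assembly, 180.0, 0.01)


def test_contact_count_monotone_through_onset(prototype_assembly, onset90):
    k90, _ = onset90
    counts = []
    for k in np.linspace(0.5 * k90, 2.0 * k90, 5):
        g = ca.detect_contacts(ca.bend(prototype_assembly, 90.0, float(k)))
        counts.append(g.number_of_edges())
    assert all(a <= b for a, b in zip(counts, counts[1:]))
    assert counts[0] == 0 and counts[-1] > 0


def test_bisection_brackets_the_onset(prototype_assembly, onset90):
    k90, _ = onset90
    below = ca.detect_contacts(ca.bend(prototype_assembly, 90.0, k90 - 2e-4))
    above = ca.detect_contacts(ca.bend(prototype_assembly, 90.0, k90 + 2e-4))
    def interior_edges(g):
        return [e for e in g.edges if g.nodes[e[0]]["interior"] or g.nodes[e[1]]["interior"]]
    assert len(interior_edges(below)) == 0
    assert len(interior_edges(above)) > 0


def test_first_contact_is_diagonal(onset90):
    _, cls = onset90
    assert cls == "diagonal"


def test_hook_contacts_back_of_scale_ahead_at_phi_zero(prototype_assembly):
    """Bending along the hooks presses each hook onto the back of the scale
    diagonally ahead of it (the transient soft-regime contact)."""
    g = prototype_assembly.lattice
    st = ca.bend(prototype_assembly, 0.0, 0.03)
    cg = ca.detect_contacts(st)
    assert cg.number_of_edges() > 0
    for u, v in cg.edges:
        assert cg.edges[u, v]["neighbor_class"] == "diagonal"
        pu, pv = cg.edges[u, v]["witness"]
        yu = g.nodes[u]["site"][1]
        yv = g.nodes[v]["site"][1]
        front, wf = ((v, pv) if yv > yu else (u, pu))
        # the witness on the front scale sits behind its own hook region
        # (its back), the witness on the rear scale is on its hook
        rear_site_y = min(yu, yv)
        rear_w = pu if yu < yv else pv
        assert rear_w[1] - rear_site_y > 0  # rear scale touches with its front (hook) side


def test_separated_scales_never_interlock():
    spec = ca.AssemblySpec(
        pattern="uniform",
        params=ca.prototype_parameters(),
        scale_length=4.0,
        spacing=3.0,  # gap comparable to the scales themselves
        grid_rows=3,
        grid_cols=3,
        n_sections=16,
        n_profile=16,
    )
    asm = ca.tile_uniform(spec)
    k, cls = ca.onset_curvature(asm, 90.0, kappa_tol=5e-4)
    assert k == NO_INTERLOCKING and cls is None
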
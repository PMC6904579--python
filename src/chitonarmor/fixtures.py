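"""Synthetic test meshes.

Small deterministic geometries used by the test-suite and available to
users for sanity-checking the morphometrics pipeline: boxes, inclined
prisms with a known basal angle, a hooked prism from mid-range parameters,
a top-heavy "mushroom" (counterexample for the basal center-of-mass
property) and parameter-jittered preset variants.
"""

from __future__ import annotations

import math

import numpy as np
import trimesh

from .errors import ParameterError
from .loft import ScaleMesh, loft_scale
from .params import ScaleParameters
from .presets import DEFAULT_PRESET, load_preset

__all__ = ["generate_fixtures", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("box", "inclined_prism", "hooked_prism", "mushroom", "noisy_preset")


def generate_fixtures(kind: str, seed: int = 0, **kwargs) -> list[ScaleMesh]:
    """Deterministic fixture meshes of the requested kind.

    box(width, length, height) — axis-aligned box, base at z=0.
    inclined_prism(beta_deg, ...) — box sheared so the basal edge makes the
        given angle with the base plane.
    hooked_prism(...) — a mid-range parametric scale at reduced resolution.
    mushroom() — thin stalk with a heavy cap (centroid above the "h1" step).
    noisy_preset(preset, sigma, n) — preset parameters with relative
        Gaussian jitter, reproducible for a given seed.
    """
    if kind not in FIXTURE_KINDS:
        raise ParameterError(f"unknown fixture kind {kind!r}; one of {FIXTURE_KINDS}")
    return _BUILDERS[kind](seed, **kwargs)


def _base_at_origin(tm: trimesh.Trimesh) -> trimesh.Trimesh:
    lo, hi = tm.bounds
    tm.apply_translation([-(lo[0] + hi[0]) / 2, -(lo[1] + hi[1]) / 2, -lo[2]])
    return tm


def _box(seed, width=1.0, length=1.0, height=1.0):
    tm = _base_at_origin(trimesh.creation.box((width, length, height)))
    return [ScaleMesh(tm, provenance="fixture:box")]


def _inclined_prism(seed, beta_deg=30.0, width=1.0, length=1.0, height=1.0):
    tm = _base_at_origin(trimesh.creation.box((width, length, height)))
    shear = np.eye(4)
    shear[1, 2] = 1.0 / math.tan(math.radians(beta_deg))  # y += z*cot(beta)
    tm.apply_transform(shear)
    return [ScaleMesh(tm, provenance="fixture:inclined_prism")]


def _hooked_prism(seed, n_sections=32, n_profile=32):
    params = ScaleParameters(
        width=0.5,
        length=1.0,
        fillet_front=0.04,
        fillet_side=0.04,
        beta_deg=40.0,
        h1=0.22,
        height=0.6,
        alpha_deg=105.0,
        hook_reach=0.05,
        tip_height_frac=0.8,
        back_inflection_frac=0.55,
        apex_shift_frac=0.6,
        under_bulge_frac=0.1,
        back_bulge_frac=0.1,
        shoulder_width_frac=0.85,
        shoulder_height_frac=0.32,
        crown_roundness=1.0,
    )
    sm = loft_scale(params, n_sections, n_profile)
    return [ScaleMesh(sm.mesh, "fixture:hooked_prism", params, sm.curves)]


def _mushroom(seed, stalk_radius=0.1, cap_radius=0.45, split=0.7, height=1.0):
    profile = np.array(
        [
            [0.0, 0.0],
            [stalk_radius, 0.0],
            [stalk_radius, split * height],
            [cap_radius, split * height],
            [cap_radius, height],
            [0.0, height],
        ]
    )
    tm = trimesh.creation.revolve(profile, sections=48)
    tm = _base_at_origin(tm)
    return [ScaleMesh(tm, provenance="fixture:mushroom")]


def _noisy_preset(seed, preset=DEFAULT_PRESET, sigma=0.02, n=3, n_sections=32, n_profile=32):
    rng = np.random.default_rng(seed)
    base = load_preset(preset).params
    jitter_keys = ("width", "length", "height", "h1", "beta_deg", "alpha_deg", "hook_reach")
    out = []
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        vals = base.free_values()
        for k in jitter_keys:
            vals[k] = vals[k] * float(1.0 + sigma * rng.standard_normal())
        try:
            p = ScaleParameters(**vals).validate_invariants()
            sm = loft_scale(p, n_sections, n_profile)
        except Exception:
            continue
        out.append(ScaleMesh(sm.mesh, f"fixture:noisy_preset:{preset}", p, sm.curves))
    if len(out) < n:
        raise ParameterError(f"could not generate {n} valid jittered variants (sigma={sigma})")
    return out


_BUILDERS = {
    "box": _box,
    "inclined_prism": _inclined_prism,
    "hooked_prism": _hooked_prism,
    "mushroom": _mushroom,
    "noisy_preset": _noisy_preset,
}
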
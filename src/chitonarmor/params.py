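"""Parameter schema for the chiton girdle-scale model.

A dorsal girdle scale is described by three principal sections — a filleted
diamond BASE outline, a sagittal YZ outline (the hooked silhouette) and a
transverse XZ outline (the crown half-width profile).  Twenty geometric
markers on those sections are positioned by exactly 17 free parameters; the
remaining marker coordinates are inherited (BASE supplies the two YZ base
corners, BASE and YZ supply the XZ base corners and crown height).

Conventions (canonical local frame):
  +Z dorsal (normal N), +Y hook / overlap direction (radial R), +X
  circumferential C.  The base centroid sits at the origin, units are mm.

Angle conventions:
  beta_deg  — inclination: angle between the posterior basal edge of the
              transverse silhouette and the base plane.  The prismatic base
              leans toward the hook, so small beta means a strong lean.
  alpha_deg — imbrication: interior angle at the anterior inflection point
              between the downward basal edge direction and the hook axis
              (the tip tangent).  The tip tangent therefore makes an angle
              of (alpha + beta - 180) degrees with the base plane, and
              alpha + beta < 180 means the hook curls past horizontal and
              can overlap the scale in front of it.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, ConfigDict, ValidationError as _PydanticValidationError

from .errors import ParameterError

#: Free parameters, grouped by the principal section they act on.
BASE_PARAMS = ("width", "length", "fillet_front", "fillet_side")
YZ_PARAMS = (
    "beta_deg",
    "h1",
    "height",
    "alpha_deg",
    "hook_reach",
    "tip_height_frac",
    "back_inflection_frac",
    "apex_shift_frac",
    "under_bulge_frac",
    "back_bulge_frac",
)
XZ_PARAMS = ("shoulder_width_frac", "shoulder_height_frac", "crown_roundness")
FREE_PARAMS = BASE_PARAMS + YZ_PARAMS + XZ_PARAMS

#: Marker labels (20 in total): 8 on BASE, 7 on YZ, 5 on XZ.
BASE_MARKERS = (
    "base_front",
    "base_back",
    "base_left",
    "base_right",
    "fillet_front_mid",
    "fillet_back_mid",
    "fillet_left_mid",
    "fillet_right_mid",
)
YZ_MARKERS = (
    "yz_back_inflection",
    "yz_back_mid",
    "yz_apex",
    "yz_crown",
    "yz_tip",
    "yz_under",
    "yz_front_inflection",
)
XZ_MARKERS = (
    "xz_base_left",
    "xz_base_right",
    "xz_shoulder_left",
    "xz_shoulder_right",
    "xz_crown",
)
ALL_MARKERS = BASE_MARKERS + YZ_MARKERS + XZ_MARKERS


class LocalFrame(BaseModel):
    """Right-handed orthonormal frame (+Z dorsal, +Y hook, +X circumferential)."""

    model_config = ConfigDict(arbitrary_types_allowed=True, frozen=True)

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: tuple[
        tuple[float, float, float],
        tuple[float, float, float],
        tuple[float, float, float],
    ] = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

    def matrix(self) -> np.ndarray:
        return np.asarray(self.axes, dtype=float)

    def validate_frame(self, tol: float = 1e-9) -> None:
        m = self.matrix()
        if not np.allclose(m @ m.T, np.eye(3), atol=tol):
            raise ParameterError("LocalFrame axes are not orthonormal")
        if np.linalg.det(m) < 1.0 - tol:
            raise ParameterError("LocalFrame is not right-handed")


class ScaleParameters(BaseModel):
    """The 17 free parameters of the parametric scale model.

    Unknown keys are rejected so that mistyped parameter files fail loudly.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    # BASE (4): filleted diamond footprint
    width: float  # W, mm — lateral (X) extent of the base diamond
    length: float  # L, mm — fore-aft (Y) extent of the base diamond
    fillet_front: float  # mm, arc radius at front/back diamond vertices
    fillet_side: float  # mm, arc radius at left/right diamond vertices

    # YZ (10): sagittal silhouette
    beta_deg: float  # inclination angle, degrees in (0, 90]
    h1: float  # mm, height of the anterior inflection (prism -> hook)
    height: float  # H, mm — apex height; h2 = H - h1
    alpha_deg: float  # imbrication angle, degrees in (0, 180]
    hook_reach: float  # mm, Y offset of the hook tip from the inflection
    tip_height_frac: float  # tip z as a fraction of H
    back_inflection_frac: float  # posterior edge stays straight up to this * H
    apex_shift_frac: float  # apex Y between posterior inflection and tip
    under_bulge_frac: float  # underside mid-marker offset (negative = S-curve)
    back_bulge_frac: float  # posterior crown mid-marker outward offset

    # XZ (3): transverse crown profile
    shoulder_width_frac: float  # shoulder half-width as a fraction of W/2
    shoulder_height_frac: float  # shoulder height as a fraction of H
    crown_roundness: float  # >1 fuller crown, <1 pointier; exponent on profile

    # ---------------------------------------------------------------- derived
    @property
    def h2(self) -> float:
        return self.height - self.h1

    @property
    def is_prismatic(self) -> bool:
        """True for the degenerate straight-extrusion family (no hook)."""
        return self.alpha_deg >= 180.0 - 1e-9

    @property
    def tip_tangent_deg(self) -> float:
        """Angle of the hook axis (tip tangent) above the base plane."""
        return self.alpha_deg + self.beta_deg - 180.0

    @property
    def shear(self) -> float:
        """Horizontal (Y) offset of the prismatic base per unit height."""
        if self.beta_deg >= 90.0 - 1e-12:
            return 0.0
        return 1.0 / math.tan(math.radians(self.beta_deg))

    def footprint_extents(self) -> tuple[float, float]:
        """Realized (width, length) extents of the filleted base footprint.

        Corner fillets pull the diamond extremes inward; morphometric W and
        L measured from a lofted mesh correspond to these extents, not to
        the nominal vertex-to-vertex ``width``/``length``.
        """
        half_front = math.atan2(self.width / 2.0, self.length / 2.0)
        half_side = math.atan2(self.length / 2.0, self.width / 2.0)
        dl = self.fillet_front * (1.0 / math.sin(half_front) - 1.0)
        dw = self.fillet_side * (1.0 / math.sin(half_side) - 1.0)
        return self.width - 2.0 * dw, self.length - 2.0 * dl

    def free_values(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in FREE_PARAMS}

    def scaled(self, s: float) -> "ScaleParameters":
        """Similarity-scale every length parameter by ``s`` (angles, fractions fixed)."""
        if s <= 0:
            raise ParameterError(f"scale factor must be positive, got {s}")
        lengths = {
            "width",
            "length",
            "fillet_front",
            "fillet_side",
            "h1",
            "height",
            "hook_reach",
        }
        vals = {k: (v * s if k in lengths else v) for k, v in self.free_values().items()}
        return ScaleParameters(**vals)

    # ------------------------------------------------------------- validation
    def validate_invariants(self) -> "ScaleParameters":
        """Raise :class:`ParameterError` naming the offending parameter."""
        for name in ("width", "length", "height", "h1"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("fillet_front", "fillet_side"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not self.h1 < self.height:
            raise ParameterError(
                f"h1 must satisfy 0 < h1 < height, got h1={self.h1}, height={self.height}"
            )
        if not 0.0 < self.beta_deg <= 90.0:
            raise ParameterError(f"beta_deg must be in (0, 90], got {self.beta_deg}")
        if not 0.0 < self.alpha_deg <= 180.0:
            raise ParameterError(f"alpha_deg must be in (0, 180], got {self.alpha_deg}")
        if self.is_prismatic:
            # Degenerate vertical-extrusion family: the base must not lean and
            # the hook parameters must vanish.
            if abs(self.beta_deg - 90.0) > 1e-9 or abs(self.hook_reach) > 1e-12:
                raise ParameterError(
                    "alpha_deg=180 is reserved for the straight-prism family "
                    "(requires beta_deg=90 and hook_reach=0)"
                )
        elif self.alpha_deg + self.beta_deg >= 180.0:
            raise ParameterError(
                "non-overlapping geometry: alpha_deg + beta_deg must be < 180 deg "
                f"(got {self.alpha_deg + self.beta_deg:.2f})"
            )
        if not 0.0 < self.tip_height_frac < 1.0 and not self.is_prismatic:
            raise ParameterError(
                f"tip_height_frac must be in (0, 1), got {self.tip_height_frac}"
            )
        if not 0.0 < self.back_inflection_frac < 1.0 and not self.is_prismatic:
            raise ParameterError(
                f"back_inflection_frac must be in (0, 1), got {self.back_inflection_frac}"
            )
        if not 0.0 <= self.apex_shift_frac <= 1.0:
            raise ParameterError(f"apex_shift_frac must be in [0, 1], got {self.apex_shift_frac}")
        if not 0.0 < self.shoulder_width_frac <= 1.0:
            raise ParameterError(
                f"shoulder_width_frac must be in (0, 1], got {self.shoulder_width_frac}"
            )
        if not 0.0 < self.shoulder_height_frac < 1.0:
            raise ParameterError(
                f"shoulder_height_frac must be in (0, 1), got {self.shoulder_height_frac}"
            )
        if not 0.25 <= self.crown_roundness <= 4.0:
            raise ParameterError(
                f"crown_roundness must be in [0.25, 4], got {self.crown_roundness}"
            )
        # Fillet arcs must fit on the diamond half-edges.
        half_edge = 0.5 * math.hypot(self.width / 2.0, self.length / 2.0)
        for name in ("fillet_front", "fillet_side"):
            r = getattr(self, name)
            if r > 0 and _fillet_tangent_offset(self.width, self.length, name, r) > half_edge:
                raise ParameterError(f"{name}={r} too large for the base diamond edges")
        return self

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_dict(cls, data: dict) -> "ScaleParameters":
        """Schema-validated construction; unknown keys are listed in the error."""
        if not isinstance(data, dict):
            raise ParameterError(f"parameter data must be a mapping, got {type(data).__name__}")
        unknown = sorted(set(data) - set(FREE_PARAMS))
        if unknown:
            raise ParameterError(
                f"unknown parameter keys: {unknown}; expected a subset of {list(FREE_PARAMS)}"
            )
        try:
            params = cls(**data)
        except _PydanticValidationError as exc:
            raise ParameterError(f"invalid parameter file: {exc}") from exc
        return params.validate_invariants()

    @classmethod
    def prism(cls, width: float, length: float, height: float) -> "ScaleParameters":
        """Degenerate parameter set whose loft is a right prism over BASE."""
        return cls(
            width=width,
            length=length,
            fillet_front=0.0,
            fillet_side=0.0,
            beta_deg=90.0,
            h1=height * 0.999999,
            height=height,
            alpha_deg=180.0,
            hook_reach=0.0,
            tip_height_frac=1.0,
            back_inflection_frac=1.0,
            apex_shift_frac=0.5,
            under_bulge_frac=0.0,
            back_bulge_frac=0.0,
            shoulder_width_frac=1.0,
            shoulder_height_frac=0.5,
            crown_roundness=1.0,
        )


def _fillet_tangent_offset(width: float, length: float, which: str, radius: float) -> float:
    """Distance from a diamond vertex to the fillet tangency point."""
    # Interior half-angle at the front/back vertices and the side vertices.
    half = math.atan2(width / 2.0, length / 2.0)  # at front/back vertex
    if which == "fillet_side":
        half = math.atan2(length / 2.0, width / 2.0)
    return radius / math.tan(half)
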
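"""Species preset registry.

Ten bundled parameter sets calibrated to the published morphometric ranges
of dorsal girdle scales from two chiton families.  Each preset records the
17 model parameters plus the descriptor windows its generated mesh is
expected to satisfy (length ratios, angles, overlap ratio, volume in mm^3).

The windows are registry metadata, not physical constants: they encode the
"ca." ranges reported for each species and are used by ``check`` and the
test-suite to guard against calibration drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .errors import ParameterError
from .params import ScaleParameters

__all__ = [
    "SpeciesPreset",
    "load_preset",
    "list_presets",
    "prototype_parameters",
    "DEFAULT_PRESET",
]

DEFAULT_PRESET = "rhyssoplax_canariensis"


@dataclass(frozen=True)
class SpeciesPreset:
    key: str
    species: str
    family: str  # Chitonidae | Ischnochitonidae
    double_curved: bool
    params: ScaleParameters
    expected: dict[str, tuple[float, float]]

    def check(self, record) -> list[str]:
        """Return the list of descriptor-window violations for a record."""
        bad = []
        for key, (lo, hi) in self.expected.items():
            val = getattr(record, key)
            if not lo <= val <= hi:
                bad.append(f"{key}={val:.4g} outside [{lo}, {hi}]")
        if self.double_curved != ("multi-inflection" in record.flags):
            want = "double-curved" if self.double_curved else "single-curved"
            bad.append(f"curvature class mismatch (expected {want})")
        return bad


def _preset_dir():
    return resources.files("chitonarmor").joinpath("data/presets")


def list_presets() -> list[str]:
    """Keys of all bundled species presets."""
    return sorted(
        p.name.removesuffix(".yaml") for p in _preset_dir().iterdir() if p.name.endswith(".yaml")
    )


def prototype_parameters() -> ScaleParameters:
    """Parameters of the printed-prototype scale (unit base length).

    A single-curved hook with h1/H = 0.5, calibrated so that scaling the
    base footprint length to 10 mm puts the inflection (embedded) height at
    4.1 mm — the dimensions of the mechanical-test panels.
    """
    path = resources.files("chitonarmor").joinpath("data/prototype.yaml")
    doc = yaml.safe_load(path.read_text())
    return ScaleParameters.from_dict(doc["parameters"])


def load_preset(key: str) -> SpeciesPreset:
    path = _preset_dir().joinpath(key + ".yaml")
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise ParameterError(
            f"unknown preset {key!r}; available: {list_presets()}"
        ) from None
    doc = yaml.safe_load(text)
    params = ScaleParameters.from_dict(doc["parameters"])
    expected = {k: (float(v[0]), float(v[1])) for k, v in doc["expected"].items()}
    return SpeciesPreset(
        key=key,
        species=doc["species"],
        family=doc["family"],
        double_curved=bool(doc.get("double_curved", False)),
        params=params,
        expected=expected,
    )
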
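import numpy as np
import pytest

import chitonarmor as ca


@pytest.fixture(scope="session")
def rc_preset():
    return ca.load_preset("rhyssoplax_canariensis")


@pytest.fixture(scope="session")
def rc_mesh(rc_preset):
    """Default-resolution R. canariensis scale mesh."""
    return ca.loft_scale(rc_preset.params, 64, 64)


@pytest.fixture(scope="session")
def rc_record(rc_mesh):
    return ca.measure(rc_mesh)


@pytest.fixture(scope="session")
def preset_records():
    """key -> (preset, record) for all ten species at working resolution."""
    out = {}
    for key in ca.list_presets():
        pr = ca.load_preset(key)
        rec = ca.measure(ca.loft_scale(pr.params, 48, 48))
        out[key] = (pr, rec)
    return out


@pytest.fixture(scope="session")
def prototype_assembly():
    """Reduced 5x5 printed-prototype panel for bending unit tests."""
    spec = ca.AssemblySpec(
        pattern="uniform",
        params=ca.prototype_parameters(),
        scale_length=10.0,
        spacing=0.5,
        grid_rows=5,
        grid_cols=5,
        n_sections=20,
        n_profile=20,
        embedded_height=4.1,
    )
    return ca.tile_uniform(spec)


@pytest.fixture(scope="session")
def rc_assembly():
    """Small uniform R. canariensis assembly (coverage / substrate tests)."""
    spec = ca.AssemblySpec(
        pattern="uniform",
        preset="rhyssoplax_canariensis",
        scale_length=10.0,
        spacing=0.5,
        grid_rows=3,
        grid_cols=3,
        n_sections=24,
        n_profile=24,
        embedded_height=4.1,
    )
    return ca.tile_uniform(spec)
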
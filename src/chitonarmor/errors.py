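"""Error classes shared across the package.

Two broad failure families are distinguished so the CLI can map them to
distinct exit codes: invalid *inputs* (parameters, specs, files) and
failures of the *geometry kernel* itself.
"""


class ChitonArmorError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParameterError(ChitonArmorError, ValueError):
    """A parameter set, assembly spec or input file violates its contract."""

    exit_code = 2


class GeometryError(ChitonArmorError, RuntimeError):
    """A geometric construction failed (degenerate section, bad mesh, ...)."""

    exit_code = 3
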
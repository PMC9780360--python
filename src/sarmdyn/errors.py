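"""Exception hierarchy shared by all pipeline stages."""


class SarmdynError(Exception):
    """Base class for all package-specific errors."""


class InputError(SarmdynError, ValueError):
    """Invalid user-supplied input (file, value, or argument)."""


class EmptyStructureError(InputError):
    """A structure file contained no polymer atoms."""


class EmptySelectionError(InputError):
    """An atom selection matched nothing."""


class InsufficientDataError(InputError):
    """Too few data points for the requested fit or computation."""


class ConfigError(SarmdynError, ValueError):
    """Malformed or inconsistent run configuration."""
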
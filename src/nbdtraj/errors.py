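"""Exception hierarchy used across the toolkit."""


class NbdtrajError(Exception):
    """Base class for all toolkit errors."""


class FormatError(NbdtrajError, ValueError):
    """A structure/trajectory file violates the expected format."""


class SelectionError(NbdtrajError, ValueError):
    """An atom selection cannot be resolved on a structure."""


class DegenerateGeometryError(NbdtrajError, ValueError):
    """Point set too small or collinear for a rigid-body fit."""


class ConfigError(NbdtrajError, ValueError):
    """Invalid analysis configuration."""
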
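"""Exception hierarchy shared across the pipeline stages."""


class GobiasError(Exception):
    """Base class for all package-specific errors."""


class OboParseError(GobiasError):
    """Malformed OBO content (missing header, term without namespace, ...)."""


class OboStructureError(GobiasError):
    """Structurally invalid ontology: cycles, ambiguous roots, unreachable terms."""


class GafFormatError(GobiasError):
    """Malformed GAF row; carries the 1-based line number in the message."""


class InsufficientDataError(GobiasError):
    """Not enough data points for a statistical operation."""


class ConfigError(GobiasError):
    """Invalid generator or pipeline configuration."""
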
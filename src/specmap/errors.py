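"""Exception hierarchy for specmap."""


class SpecmapError(Exception):
    """Base class for all specmap errors."""


class AlignmentFormatError(SpecmapError):
    """A sequence file could not be parsed, or contains invalid characters."""


class DimensionError(SpecmapError):
    """Rows of an alignment (or paired data vectors) have mismatched lengths."""


class LookupError_(SpecmapError):
    """A sequence id, leaf name, or column was not found."""


class DegenerateInputError(SpecmapError):
    """Input is structurally valid but carries no usable signal."""


class FitError(SpecmapError):
    """Nonlinear regression failed to converge or the design is uninformative."""


class ConfigError(SpecmapError):
    """A run configuration is missing, malformed, or contains unknown keys."""
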
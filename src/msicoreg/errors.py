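"""Exception hierarchy shared across the package."""


class MsicoregError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MsicoregError):
    """A file or in-memory object does not conform to the expected format."""


class DimensionError(MsicoregError):
    """Array shapes of two inputs that must agree do not."""


class ConfigError(MsicoregError):
    """A configuration value is out of its admissible range."""


class DegenerateInputError(MsicoregError):
    """An input is valid in shape but degenerate in content (constant image,
    empty mask, zero-variance support, ...)."""
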
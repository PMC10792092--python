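"""Exception hierarchy shared across the package."""


class VibramanError(Exception):
    """Base class for all package-specific errors."""


class ParseError(VibramanError):
    """A file could not be parsed; the message names the offending line."""


class FormatError(VibramanError):
    """A file is structurally not in the expected format."""


class SchemaError(VibramanError):
    """A domain object violates one of its invariants."""


class DomainError(VibramanError):
    """A numeric input falls outside the physically meaningful domain."""


class AttributionError(VibramanError):
    """A mode cannot be attributed to a fragment."""


class GridError(VibramanError):
    """Spectra live on incompatible grids, or a grid spec is invalid."""


class NormalizationError(VibramanError):
    """A spectrum cannot be normalized (all zero or all missing)."""


class PackagingError(VibramanError):
    """A packaged data file failed its integrity check."""
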
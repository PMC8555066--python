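"""Exception types shared across the pipeline."""


class MetastrackError(Exception):
    """Base class for all pipeline errors."""


class FormatError(MetastrackError):
    """An input file lacks a required field or is malformed."""


class ConfigurationError(MetastrackError):
    """User-supplied configuration is inconsistent with the data."""


class DataError(MetastrackError):
    """Input data violates a structural precondition (e.g. overlapping segments)."""


class UsageError(MetastrackError):
    """An operation was called on inputs it is not defined for."""


class AmbiguousStateError(MetastrackError):
    """Allele-state voting fell below the required majority; no silent call."""


class DegenerateMatrixError(MetastrackError):
    """Conflict removal exhausted too many samples; the data likely violates
    the infinite-sites assumption globally rather than in a few mixtures."""
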
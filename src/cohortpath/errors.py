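"""Exception hierarchy shared across the pipeline stages."""


class CohortPathError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CohortPathError):
    """An input specification or config block is invalid; message names the field."""


class FormatError(CohortPathError):
    """A file does not conform to its expected dialect; message names the line."""


class DesignError(CohortPathError):
    """A differential-expression design is unusable (e.g. a group with < 2 samples)."""


class NumericRangeError(CohortPathError):
    """A transformation produced non-finite values."""


class DegenerateVarianceError(CohortPathError):
    """All residual variances are zero; variance moderation is undefined."""


class GuidanceError(CohortPathError):
    """All walker guide mass falls outside the walked network component."""


class LookupError_(CohortPathError):
    """An identifier (pathway, gene set) is unknown to the collection."""
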
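"""Exception hierarchy shared across the package."""


class RiverDriftError(Exception):
    """Base class for all riverdrift errors."""


class ValidationError(RiverDriftError):
    """A data object violates one of its invariants."""


class SchemaError(ValidationError):
    """An input file is missing required columns or sections."""


class ParseError(RiverDriftError):
    """A cell or token could not be parsed; the message names the location."""


class PipelineOrderError(RiverDriftError):
    """A preprocessing operation was applied out of its mandated order."""


class ConstantSeriesError(RiverDriftError):
    """Pearson correlation requested on a zero-variance series.

    Raised deliberately (and distinctly from any numerical failure) so callers
    can turn the degenerate case into a flagged NaN where that is the
    documented behaviour.
    """
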
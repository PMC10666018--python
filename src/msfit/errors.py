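"""Exception hierarchy shared across the package."""


class MSFitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MSFitError):
    """A stream, catalog, or log file does not conform to its format."""


class ParameterError(MSFitError, ValueError):
    """An operation was called with out-of-domain parameters."""


class DegenerateGeometryError(MSFitError):
    """A joint-angle computation hit a zero-length bone vector."""


class TemplateError(MSFitError):
    """A gesture template violates its invariants (e.g. zero range of motion)."""


class ScoringError(MSFitError):
    """Scoring could not proceed (e.g. a scored joint series is missing)."""


class ValidationError(MSFitError):
    """Domain-type invariant violated (scores out of range, bad category, ...)."""
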
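"""Exception hierarchy for the planning pipeline.

All user-facing failures derive from :class:`Ms2PathError` so the CLI can map
them onto a single nonzero exit code with a one-line diagnostic.
"""


class Ms2PathError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(Ms2PathError):
    """A table is missing a required column or has an unusable layout."""


class ParseError(Ms2PathError):
    """A table cell could not be parsed as the expected type."""


class ValidationError(Ms2PathError):
    """Input data violate a documented invariant (e.g. duplicate feature ids)."""


class ConfigurationError(Ms2PathError):
    """A parameter combination is unusable (e.g. empty apex list for clustering)."""


class DegenerateFitError(Ms2PathError):
    """The TIC regression has no unique solution (all abscissae identical)."""


class ConstraintViolationError(ValidationError):
    """An acquisition schedule violates one of the scheduling constraints.

    The message names the violated constraint number: (3) single contiguous
    acquisition interval per feature, (4) at most one acquisition per time bin,
    (5) binary assignments.
    """


class NoFeasibleAcquisitionError(Ms2PathError):
    """No feature admits any acquisition window above the TIC threshold."""
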
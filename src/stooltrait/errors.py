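"""Exception hierarchy for pipeline failure modes.

Every error raised by this package derives from :class:`StoolTraitError`, so
callers can catch one type at the pipeline boundary while tests can assert
the specific degenerate condition.
"""


class StoolTraitError(Exception):
    """Base class for all errors raised by stooltrait."""


class InvalidInputError(StoolTraitError, ValueError):
    """Input violates a documented precondition (shape, dtype, range, emptiness)."""


class DegenerateMaskError(StoolTraitError):
    """A binary mask has no pixels in the region an operation requires."""


class DegenerateHistogramError(StoolTraitError):
    """A grayscale map is constant: every threshold yields zero inter-class variance."""


class DegenerateIlluminationError(StoolTraitError):
    """Background illumination estimate is zero (all-black background)."""


class CannotSplitError(StoolTraitError):
    """Too few shape groups to form both a training and a testing partition."""
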
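"""Exception types shared across the package."""


class MarkerDeconError(Exception):
    """Base class for all markerdecon errors."""


class FormatError(MarkerDeconError):
    """A delimited input file does not match the expected layout."""


class EmptyReferenceError(MarkerDeconError):
    """Duplicate removal left no unique marker genes."""


class EmptyResultError(MarkerDeconError):
    """An operation produced an empty table where data are required."""


class ValidationError(MarkerDeconError):
    """A domain object violates one of its invariants."""
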
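"""Exception hierarchy shared across the toolkit."""


class SccycleError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(SccycleError, ValueError):
    """Input data violates a documented precondition or invariant."""


class IdentityMismatchError(ValidationError):
    """Cell or gene identifiers in the matrix and metadata do not agree."""


class EmptySelectionError(SccycleError, LookupError):
    """A filter removed every cell (or gene)."""


class UnknownLabelError(SccycleError, KeyError):
    """A requested cluster/condition label does not exist in the dataset."""


class MissingTimepointError(ValidationError):
    """An operation requires cells at every distinct timepoint."""


class SplitInfeasibleError(ValidationError):
    """A half-split needs at least two cells at every timepoint."""


class DegenerateInputError(ValidationError):
    """Input is degenerate for the requested operation."""


class DegenerateTemplateError(DegenerateInputError):
    """A constant template has no shape to normalize."""
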
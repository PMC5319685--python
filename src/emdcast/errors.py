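"""Exception hierarchy.

Every reader and numeric routine raises one of these rather than silently
repairing its input; messages name the offending location (row, month,
component) wherever one exists.
"""


class EmdcastError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EmdcastError, ValueError):
    """Input violates a documented precondition (shape, length, range)."""


class DegenerateInputError(EmdcastError, ValueError):
    """Input is formally valid but the operation is undefined on it
    (constant series for min-max scaling, zero mean for a seasonal index)."""


class NotSiftableError(EmdcastError):
    """Signal has fewer than two maxima or two minima: no envelope can be
    fitted and the decomposition must terminate."""


class NumericFailureError(EmdcastError):
    """A non-finite value appeared during iterative computation."""


class GapError(EmdcastError, ValueError):
    """A monthly series has a missing calendar month."""


class ParseError(EmdcastError, ValueError):
    """A file cell or row could not be parsed."""
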
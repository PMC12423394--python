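"""Exception hierarchy for isenics.

Every error raised on a malformed or degenerate input derives from
:class:`IsenicsError`, so callers (and the CLI) can catch one type.
"""


class IsenicsError(Exception):
    """Base class for all isenics errors."""


class ParseError(IsenicsError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(IsenicsError):
    """An input violates a documented invariant."""


class InsufficientOverlapError(IsenicsError):
    """Too few signature genes survive alignment with the expression matrix."""


class UndefinedCorrelationError(IsenicsError):
    """A rank correlation is undefined (zero variance in a ranked vector)."""


class GroupSizeError(IsenicsError):
    """A grouping or test requires more units per group than were given."""
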
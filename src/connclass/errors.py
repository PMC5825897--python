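"""Exception hierarchy.

All package errors derive from :class:`ConnclassError` so callers can catch
one base; each also derives from ``ValueError`` to behave sanely in generic
code.
"""


class ConnclassError(Exception):
    """Base class for all errors raised by connclass."""


class ConfigurationError(ConnclassError, ValueError):
    """Invalid configuration value (bad band edges, unknown feature id, ...)."""


class ShapeError(ConnclassError, ValueError):
    """Array dimensions inconsistent with the operation's contract."""


class InsufficientDataError(ConnclassError, ValueError):
    """Too few subjects/observations for the requested statistic."""


class DegenerateInputError(ConnclassError, ValueError):
    """Input is constant / zero-variance where spread is required."""


class IntegrityError(ConnclassError, ValueError):
    """Internal consistency violated (asymmetric matrix, missing records)."""


class ParseError(ConnclassError, ValueError):
    """Malformed on-disk input; message carries file and line context."""
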
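"""Exception hierarchy shared across the package.

Three families map onto the CLI's distinct exit codes: bad inputs
(:class:`ValidationError`), unreadable/unwritable files
(:class:`SessionIOError`) and analyses that cannot produce a defined
result (:class:`ComputationError`).
"""


class TemplatestError(Exception):
    """Base class for all package errors."""


class ValidationError(TemplatestError, ValueError):
    """Input violates a documented precondition or invariant."""


class SessionIOError(TemplatestError, OSError):
    """A session or result file could not be read or written."""


class ComputationError(TemplatestError, RuntimeError):
    """An analysis could not produce any defined result (e.g. every
    trial excluded because of zero-variance vectors)."""
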
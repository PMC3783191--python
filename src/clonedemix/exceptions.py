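"""Package-wide exception hierarchy.

Exit-code mapping used by the CLI: :class:`InputError` -> 2,
:class:`CapExceededError` -> 3.
"""


class CloneDemixError(Exception):
    """Base class for all errors raised by this package."""


class InputError(CloneDemixError, ValueError):
    """Malformed or out-of-range user input."""


class CapExceededError(CloneDemixError):
    """A configured size/solution cap was exceeded.

    Carries an optional ``hint`` with guidance (e.g. cluster frequencies
    first to reduce the problem size).
    """

    def __init__(self, message: str, hint: str | None = None):
        super().__init__(message)
        self.hint = hint


class NumericalError(CloneDemixError):
    """A numerical routine (e.g. NNLS) failed to converge."""
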
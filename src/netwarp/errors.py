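"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: :class:`InputError` -> 1,
:class:`NumericalError` -> 2.
"""


class NetwarpError(Exception):
    """Base class for all package-specific errors."""


class InputError(NetwarpError):
    """Malformed, empty, or inconsistent user input."""


class MalformedRowError(InputError):
    """A specific row of an input file could not be parsed."""

    def __init__(self, path, line_number: int, message: str):
        self.path = path
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


class EmptyNetworkError(InputError):
    """The network has no nodes/edges after parsing and filtering."""


class NumericalError(NetwarpError):
    """An iterative solver failed to converge or a system is singular."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        if residual is not None:
            message = f"{message} (last residual: {residual:.3e})"
        super().__init__(message)


class NetwarpWarning(UserWarning):
    """Base warning category for recoverable data issues."""
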
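"""Exception hierarchy shared across the package."""


class NuclevalError(Exception):
    """Base class for all errors raised by nucleval."""


class FormatError(NuclevalError):
    """A file or encoded record violates the expected format."""


class OverlapError(NuclevalError):
    """Two object masks claim the same pixel under the ``error`` policy."""


class ContractError(NuclevalError, ValueError):
    """An operation's precondition is violated (shape mismatch, empty input...)."""


class GenerationError(NuclevalError):
    """The synthetic generator could not satisfy a placement constraint."""
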
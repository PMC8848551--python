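"""Typed exceptions shared across the package."""


class BnforgeError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(BnforgeError, ValueError):
    """A precondition on an argument was violated."""


class DegenerateDrawError(BnforgeError, RuntimeError):
    """Random construction failed to produce a non-degenerate object
    within the retry budget."""


class EventSpaceTooLargeError(BnforgeError, ValueError):
    """The joint event space exceeds the exact-enumeration cap."""

    def __init__(self, size: int, cap: int):
        self.size = size
        self.cap = cap
        super().__init__(
            f"joint event space has {size} events, exceeding the exact "
            f"enumeration cap of {cap}; raise the cap only if memory allows"
        )


class BoundNotAttainedError(BnforgeError, RuntimeError):
    """A sample-size search reached its cap without meeting the bound."""

    def __init__(self, cap: int, message: str | None = None):
        self.cap = cap
        super().__init__(
            message or f"required sample size not attained within cap N={cap}"
        )


class UndefinedConditionalError(BnforgeError, ZeroDivisionError):
    """Conditioning event has probability zero; the conditional is undefined."""


class ModelFormatError(BnforgeError, ValueError):
    """A serialized model file violates the schema or model invariants."""


class DataIntegrityError(BnforgeError, ValueError):
    """A dataset contains values inconsistent with the model."""
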
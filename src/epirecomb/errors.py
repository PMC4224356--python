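"""Exception types shared across the package."""


class EpirecombError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(EpirecombError, ValueError):
    """A parameter violates its documented domain (e.g. non-positive window size)."""


class LayoutMismatchError(EpirecombError, ValueError):
    """Two objects bound to different genome layouts were combined."""


class InvalidMapError(EpirecombError, ValueError):
    """A synteny map violates its invariants (length mismatch, overlapping source blocks)."""


class PlacementError(EpirecombError, RuntimeError):
    """No eligible placement exists for an interval of a given length."""

    def __init__(self, length: int, message: str | None = None):
        self.length = length
        super().__init__(message or f"no eligible placement for an interval of length {length}")


class DegenerateInputError(EpirecombError, ValueError):
    """Statistical input with no usable variation (zero variance, zero margin, ...)."""


class UnderdeterminedError(EpirecombError, ValueError):
    """Too few observations for the requested model."""


class PairingError(EpirecombError, ValueError):
    """Paired region lists of unequal length."""


class GenerationError(EpirecombError, RuntimeError):
    """A synthetic-data generator cannot satisfy the requested configuration."""


class StageError(EpirecombError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage:{stage}] {message}")


class ValidationError(EpirecombError, ValueError):
    """A file failed validation; carries path and line number where known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f"{path}"
            if line is not None:
                where += f":{line}"
            where = f" ({where})"
        super().__init__(message + where)
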
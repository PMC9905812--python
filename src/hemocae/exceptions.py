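"""Exception hierarchy shared across the package."""


class HemocaeError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(HemocaeError, ValueError):
    """An argument is outside its documented domain."""


class ShapeError(HemocaeError, ValueError):
    """Array dimensions are inconsistent with the model or operation."""


class DataError(HemocaeError, ValueError):
    """A dataset is empty or structurally invalid."""


class DivergenceError(HemocaeError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class AssemblyError(HemocaeError, ValueError):
    """Sub-model dimensions do not chain into a composite model."""
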
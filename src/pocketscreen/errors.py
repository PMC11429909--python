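"""Exception hierarchy for pocketscreen."""


class PocketScreenError(Exception):
    """Base class for all pocketscreen errors."""


class EmptyStructureError(PocketScreenError):
    """A structure contained no usable atom records."""


class DegenerateGeometryError(PocketScreenError):
    """Input geometry is degenerate for the requested operation."""


class GridBudgetError(PocketScreenError):
    """The requested voxel grid exceeds the configured budget."""


class FitConvergenceError(PocketScreenError):
    """A model fit failed to converge; carries diagnostics in ``details``."""

    def __init__(self, message, details=None):
        super().__init__(message)
        self.details = details or {}


class ValidationError(PocketScreenError):
    """Invalid user input (bad thresholds, mismatched tables, ...)."""
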
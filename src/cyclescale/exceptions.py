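"""Exception hierarchy for cyclescale.

All package errors derive from :class:`CycleScaleError` so that callers can
catch everything cycle-related with a single except clause while still being
able to distinguish the stage that failed.
"""


class CycleScaleError(Exception):
    """Base class for all cyclescale errors."""


class InputError(CycleScaleError):
    """Malformed or missing input (file, column, parameter)."""


class ValidationError(CycleScaleError):
    """Data violates a structural invariant (non-finite values, bad shapes)."""


class SegmentationError(CycleScaleError):
    """Cycle segmentation failed (too few cycles, degenerate signal)."""


class FlatSpectrumError(SegmentationError):
    """No dominant spectral peak; the period cannot be inferred automatically."""


class ConnectivityError(CycleScaleError):
    """The cycle similarity graph is disconnected."""


class IsolatedCycleError(ConnectivityError):
    """A cycle has zero total similarity to every other cycle."""


class DegenerateGeometryError(CycleScaleError):
    """Distance geometry admits no one-dimensional embedding."""


class DegenerateFitError(CycleScaleError):
    """A least-squares fit is singular (constant predictor, zero variance)."""


class FitError(CycleScaleError):
    """A spectral fit has too few usable ordinates."""


class IntegrationError(CycleScaleError):
    """Numerical integration diverged."""
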
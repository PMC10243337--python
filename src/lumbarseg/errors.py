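"""Exception hierarchy for the lumbar segmentation pipeline.

Every error raised on a contract violation derives from :class:`LumbarSegError`
so callers can catch pipeline failures without swallowing programming errors.
"""


class LumbarSegError(Exception):
    """Base class for all package-specific errors."""


class DimensionalityError(LumbarSegError):
    """Input grid does not have exactly three spatial axes."""


class FormatError(LumbarSegError):
    """File content violates the expected format (spacing, value types)."""


class AlignmentError(LumbarSegError):
    """Two grids that must share a lattice have different shapes."""


class LabelRangeError(LumbarSegError):
    """Label map contains values outside the allowed label set."""


class ParameterError(LumbarSegError):
    """A scalar parameter is outside its valid domain."""


class ConfigurationError(LumbarSegError):
    """A network or pipeline configuration is internally inconsistent."""


class ShapeError(LumbarSegError):
    """A tensor fed to a network violates its shape contract."""


class DataError(LumbarSegError):
    """A dataset or manifest is empty, unreadable, or inconsistent."""


class DivergenceError(LumbarSegError):
    """Training produced a non-finite loss."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite loss at training step {step}")


class EmptyROIError(LumbarSegError):
    """Localization produced no foreground; the crop stage cannot proceed."""


class BoundsError(LumbarSegError):
    """A bounding box reaches outside the grid it indexes."""


class UndefinedMetricError(LumbarSegError):
    """An overlap or surface metric is undefined (both masks empty)."""


class UndefinedSurfaceError(LumbarSegError):
    """A surface is requested for an empty mask."""


class GeometryError(LumbarSegError):
    """Phantom geometry does not fit inside the requested volume."""


class PairingError(LumbarSegError):
    """Prediction/ground-truth directories cannot be matched one-to-one."""


class CompatibilityError(LumbarSegError):
    """A checkpoint does not match the configuration it is loaded into."""
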
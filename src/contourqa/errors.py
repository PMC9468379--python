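"""Exception hierarchy for contourqa.

All toolkit errors derive from :class:`ContourQAError` so callers can catch
one base class; argument-validation failures additionally derive from
``ValueError`` and geometry/format failures carry enough context to name
the offending structure, plane or file.
"""


class ContourQAError(Exception):
    """Base class for all contourqa errors."""


class ArgumentError(ContourQAError, ValueError):
    """An argument is outside its documented domain."""


class GridMismatchError(ContourQAError):
    """Two volumes do not share one image grid."""


class CoordinateMismatchError(ContourQAError):
    """A contour plane does not map onto the target grid."""


class EmptyStructureError(ContourQAError):
    """An operation requiring a non-empty structure received an empty one."""


class UndefinedMetricError(ContourQAError):
    """The requested metric is undefined for the given inputs (e.g. Dice of
    two empty masks)."""


class DegenerateResultError(ContourQAError):
    """A perturbation would leave a degenerate (empty) structure."""


class CoverageError(ContourQAError):
    """A structure extends outside the dose grid."""

    def __init__(self, message: str, out_of_grid_fraction: float = 0.0):
        super().__init__(message)
        self.out_of_grid_fraction = out_of_grid_fraction


class BinningError(ContourQAError):
    """Two DVH curves do not share a common binning."""


class SampleSizeError(ContourQAError, ValueError):
    """A statistical test received fewer values than it requires."""


class DegenerateSampleError(ContourQAError):
    """A statistical test received a zero-variance sample."""


class GroupingError(ContourQAError):
    """A required comparison group is empty."""


class FormatError(ContourQAError):
    """A file could not be parsed as the expected interchange format."""


class UnsupportedOrientationError(FormatError):
    """The file stores an oblique (non axis-aligned) geometry."""
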
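"""Exception hierarchy for rangeshift.

Every error a pipeline stage can raise derives from :class:`RangeshiftError`
so drivers can distinguish domain failures from programming errors.
"""


class RangeshiftError(Exception):
    """Base class for all rangeshift domain errors."""


class InvalidGridError(RangeshiftError):
    """Grid specification violates its invariants (e.g. non-positive cell size)."""


class SchemaError(RangeshiftError):
    """A data container is missing required variables or columns."""


class InfeasibleSampleError(RangeshiftError):
    """Requested more occurrence cells than have positive suitability."""


class EligibilityError(RangeshiftError):
    """Species has fewer than the minimum number of distinct occupied cells."""


class DegenerateFeatureError(RangeshiftError):
    """A climate layer is constant over the background; names the variable."""


class ConvergenceError(RangeshiftError):
    """Optimizer failed to converge; carries the final gradient norm."""

    def __init__(self, message: str, grad_norm: float):
        super().__init__(message)
        self.grad_norm = grad_norm


class ProjectionError(RangeshiftError):
    """Model projected onto a stack with mismatched grid or variables."""


class AlignmentError(RangeshiftError):
    """Rasters or species lists do not share a common grid/ordering."""


class UndefinedMetricError(RangeshiftError):
    """A metric is undefined for the given input (e.g. empty range)."""


class PipelineConfigError(RangeshiftError):
    """Pipeline configuration invalid or references unresolvable paths."""
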
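"""Exception hierarchy for the ROI-consistency pipeline."""


class RoiConsistError(Exception):
    """Base class for all package errors."""


class ValidationError(RoiConsistError):
    """Input data or configuration violates a documented contract."""


class CapacityError(ValidationError):
    """Requested ROI blocks do not fit into the voxel grid."""


class ZeroVarianceError(RoiConsistError):
    """Pearson correlation is undefined because a series is constant."""


class DegenerateInputError(RoiConsistError):
    """An operation received input on which its result is undefined
    (e.g. every voxel filtered out, zero links requested)."""


class PipelineError(RoiConsistError):
    """A pipeline stage failed; the message names the stage."""
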
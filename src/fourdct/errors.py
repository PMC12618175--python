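"""Exception hierarchy shared across the package."""


class FourDCTError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FourDCTError, ValueError):
    """A configuration or function argument is out of its valid range."""


class InsufficientCyclesError(FourDCTError, ValueError):
    """Fewer than two breathing cycles could be identified in a trace."""


class OutOfBoundsError(FourDCTError, ValueError):
    """The moving target would leave the voxel grid."""


class ModeError(FourDCTError, ValueError):
    """Operation called on the wrong acquisition mode."""


class PlanError(FourDCTError, RuntimeError):
    """A scan plan cannot be built (e.g., the trace is shorter than the scan)."""


class ReconstructionError(FourDCTError, RuntimeError):
    """Phase reconstruction requested outside the available signal span."""


class ROIError(FourDCTError, ValueError):
    """Region of interest is out of bounds or overlaps another ROI."""


class UndefinedCNRError(FourDCTError, ZeroDivisionError):
    """CNR is undefined because both ROIs have zero variance."""


class EmptyStructureError(FourDCTError, ValueError):
    """A measurement was requested on an empty segmentation mask."""


class InsufficientDataError(FourDCTError, ValueError):
    """Too few observations for a statistical procedure."""
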
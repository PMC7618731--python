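"""Exception hierarchy for the fibre-pulling analysis pipeline."""


class FibremechError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FibremechError, ValueError):
    """A physical parameter is outside its admissible range (e.g. non-positive)."""


class DegenerateContactError(FibremechError):
    """Contact-curve slope is too close to zero to define an optical lever sensitivity."""


class MissingCalibrationError(FibremechError):
    """A derived calibration quantity is required but has not been computed."""


class SchemaError(FibremechError):
    """A trace table is missing required columns or has the wrong layout."""


class DataError(FibremechError):
    """Trace contents violate an invariant (e.g. non-monotone time)."""


class SegmentationError(FibremechError):
    """Phase segmentation could not find the segments the protocol requires."""


class GeometrySingularError(FibremechError, ValueError):
    """Force is undefined because the pulling angle is at or below the floor."""


class InvalidGeometryError(FibremechError, ValueError):
    """Fibre cross-section or well geometry is non-physical."""


class BaselineError(FibremechError):
    """Drift baseline cannot be estimated (no zero-strain dwells found)."""


class ComparisonPolicyError(FibremechError, ValueError):
    """A requested group comparison violates the pooling policy
    (crosslinked and uncrosslinked fibres are never combined into one
    ratio for stress-valued metrics)."""


class GroupTooSmallError(FibremechError, ValueError):
    """A statistical group has too few values for the requested test."""
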
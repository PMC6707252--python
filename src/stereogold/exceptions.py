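"""Exception hierarchy for stereogold."""


class StereogoldError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(StereogoldError, ValueError):
    """Input data or metadata violates a documented contract."""


class SizingError(StereogoldError, ValueError):
    """A requested volume or image exceeds its size budget or has non-positive dimensions."""


class CiliumNotFoundError(StereogoldError, KeyError):
    """A requested label id is absent from the label volume."""


class DegenerateGeometryError(StereogoldError, ValueError):
    """A point cloud or neighbor configuration is too symmetric/collinear to orient."""


class MeasurementError(StereogoldError, ValueError):
    """A morphometric estimate cannot be formed (e.g. empty mid-band)."""


class CorrectionError(StereogoldError, ValueError):
    """Azimuth correction is undefined for the given neighbor geometry."""


class ParameterError(StereogoldError, ValueError):
    """A parameter is outside its admissible range for the given data."""


class ConsistencyError(StereogoldError, ValueError):
    """Cross-referenced records disagree (unknown ids, mismatched grids)."""


class NormalizationError(StereogoldError, ValueError):
    """A staining profile cannot be normalized (non-positive actin reference)."""


class ProfileBoundsError(StereogoldError, ValueError):
    """A measurement box extends outside the image."""
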
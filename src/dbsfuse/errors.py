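"""Exception hierarchy for the fusion pipeline.

Every stage raises a subclass of :class:`DbsFuseError` so the CLI can map
failures to stage-named exit codes.
"""


class DbsFuseError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(DbsFuseError, ValueError):
    """A scalar parameter is outside its valid range (e.g. window <= 0)."""


class GeometryMismatchError(DbsFuseError, ValueError):
    """Two volumes were expected to share a voxel grid but do not."""


class InvalidGeometryError(DbsFuseError, ValueError):
    """Volume geometry violates an invariant (spacing, direction, shape)."""


class PairingError(DbsFuseError, ValueError):
    """Landmark sets cannot be paired (count mismatch)."""


class InsufficientLandmarksError(DbsFuseError, ValueError):
    """Fewer than three landmarks supplied to the rigid fit."""


class DegenerateConfigurationError(DbsFuseError, ValueError):
    """Landmarks are collinear (or otherwise degenerate) within tolerance."""


class DegenerateAxisError(DbsFuseError, ValueError):
    """Electrode axis endpoints coincide."""


class LandmarkParseError(DbsFuseError, ValueError):
    """A fiducial/landmark file could not be parsed."""


class InsufficientOverlapError(DbsFuseError, RuntimeError):
    """Too few metric samples map inside the moving volume."""


class RegistrationInitError(DbsFuseError, RuntimeError):
    """Initial transform leaves the volumes essentially non-overlapping."""


class PhantomSpecError(DbsFuseError, ValueError):
    """Phantom specification violates a constraint (e.g. FOV containment)."""


class PipelineConfigError(DbsFuseError, ValueError):
    """Pipeline configuration is invalid (missing files, shared landmark files)."""
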
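"""Exception hierarchy."""


class ArchTorqueError(Exception):
    """Base class for package errors."""


class ParameterError(ArchTorqueError, ValueError):
    """A physical parameter is outside its valid domain."""


class StabilityError(ArchTorqueError):
    """Integrator time step too large for the fastest relaxation time."""


class CalibrationError(ArchTorqueError):
    """Axial calibration could not be established."""


class TrackingError(ArchTorqueError):
    """An image stack could not be reduced to a trajectory."""


class GeometryError(ArchTorqueError):
    """Trajectory geometry is degenerate (no plane / insufficient rotation)."""


class IdentifiabilityError(ArchTorqueError):
    """A fit is requested on data that cannot constrain its parameters."""


class ConfigError(ArchTorqueError):
    """Invalid pipeline configuration."""
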
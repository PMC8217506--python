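"""Exception hierarchy shared across the package."""


class VesselFEError(Exception):
    """Base class for all package-specific failures."""


class ConfigError(VesselFEError):
    """Invalid or incomplete configuration."""


class CalibrationError(VesselFEError):
    """Network generation cannot satisfy the requested calibration."""


class MeshError(VesselFEError):
    """Invalid mesh, empty mesh, or a geometric operation that failed."""


class CouplingError(VesselFEError):
    """Beam-in-solid coupling could not be established."""


class SolverError(VesselFEError):
    """Explicit time integration failed (inversion, divergence)."""


class InstabilityError(SolverError):
    """Energy-balance drift exceeded the configured bound."""
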
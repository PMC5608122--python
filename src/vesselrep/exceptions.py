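"""Exception hierarchy shared across the package."""


class VesselRepError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(VesselRepError, ValueError):
    """A parameter violates its contract (non-positive timing, bad sigma, ...)."""


class InsufficientDataError(VesselRepError, ValueError):
    """Too few observations/pixels to compute the requested quantity."""


class ZeroSigmaError(VesselRepError, ValueError):
    """The noise ROI has zero spread, so SNR is undefined."""


class GeometryError(VesselRepError, ValueError):
    """Invalid, degenerate, or out-of-bounds geometry."""


class PairingError(VesselRepError, ValueError):
    """Repeat/sequence observations cannot be paired as required."""
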
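"""Exception types shared across the package."""


class NeckstickError(Exception):
    """Base class for all package-specific errors."""


class FrameMismatchError(NeckstickError):
    """A vector or pose was expressed in a different frame than expected."""


class DegenerateGeometryError(NeckstickError):
    """Marker geometry is (near-)collinear; no unique rigid-body pose exists."""


class GimbalLockError(NeckstickError):
    """The intermediate Euler angle is at +/-90 deg; the decomposition is singular."""


class IdentifiabilityError(NeckstickError):
    """The pooled linear system is rank deficient; parameters are not identifiable."""

    def __init__(self, message: str, deficient_directions=None):
        super().__init__(message)
        self.deficient_directions = deficient_directions or []


class TrialParseError(NeckstickError):
    """A trial file violates the expected plain-text trajectory format."""
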
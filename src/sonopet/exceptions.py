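"""Exception and warning types shared across the package."""


class SonopetError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SonopetError, ValueError):
    """A physical or protocol parameter is outside its valid domain."""


class InfeasibleScheduleError(SonopetError, ValueError):
    """A burst schedule cannot fit inside one grid repetition period."""


class SingularGeometryError(SonopetError, ValueError):
    """A requested evaluation point coincides with a transducer element."""


class AliasingError(SonopetError, ValueError):
    """Requested sampling rate cannot represent the synthesized bandwidth."""


class InvalidBandError(SonopetError, ValueError):
    """A frequency band lies (partly) outside the representable spectrum."""


class EmptyBandError(SonopetError, ValueError):
    """A frequency band selects no spectral bins."""


class NoSignalError(SonopetError, ValueError):
    """An operation that needs nonzero signal received an all-zero input."""


class AlignmentError(SonopetError, ValueError):
    """Traces to be combined do not share the same burst-time grid."""


class EmptyRoiError(SonopetError, ValueError):
    """A region-of-interest mask selects no voxels."""


class GeometryError(SonopetError, ValueError):
    """Volumes/masks do not share the same voxel lattice."""


class MetadataError(SonopetError, ValueError):
    """Required acquisition metadata (isotope, dose, units) is missing."""


class IncompleteTableError(SonopetError, ValueError):
    """A Ct table lacks required (group, gene) rows."""


class SteeringRangeWarning(UserWarning):
    """Drive compensation factor is implausibly large: focus is far outside
    the array's electronic steering range."""
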
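"""Exception types shared across the package."""


class MsemapError(Exception):
    """Base class for all package-specific errors."""


class DesignError(MsemapError):
    """A phantom design file or object violates its invariants."""


class DesignParseError(DesignError):
    """A design file could not be parsed; the message names the offending line."""


class LocalizationError(MsemapError):
    """Phantom placement could not be established from the detections."""


class AmbiguousLandmarksError(LocalizationError):
    """Two distinct detection triples match the landmark triangle about equally well."""


class DegenerateGeometryError(MsemapError):
    """Point configuration is degenerate (e.g. collinear) for the requested operation."""


class FitRankError(MsemapError):
    """The unregularized least-squares system is rank deficient."""


class ConvergenceError(MsemapError):
    """An iterative solver failed to converge; the message names the location."""
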
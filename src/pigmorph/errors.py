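"""Exception hierarchy shared across the package."""


class PigmorphError(Exception):
    """Base class for all package-specific errors."""


class EmptyMaskError(PigmorphError):
    """Raised when an operation receives a mask with no foreground pixels."""


class DegenerateInputError(PigmorphError):
    """Raised when a blob or contour is too small/thin for a geometric operator."""


class DegenerateSkeletonError(DegenerateInputError):
    """Raised when a blob is not elongated enough for a meaningful skeleton angle."""


class CentroidOutsideError(PigmorphError):
    """Raised when the area centroid of a blob falls on background.

    Strongly concave blobs can place their centroid outside the foreground;
    callers may retry with ``fallback_to_nearest=True`` to anchor the chord
    scan at the nearest on-mask pixel instead.
    """


class ValidationError(PigmorphError):
    """Raised on invalid arguments, malformed tables or contract violations."""


class FeatureExtractionError(PigmorphError):
    """Wraps an upstream failure, naming the feature that could not be computed."""

    def __init__(self, feature: str, cause: Exception):
        self.feature = feature
        self.cause = cause
        super().__init__(f"feature '{feature}' failed: {cause}")
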
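"""Exception hierarchy.

Every error carries a short machine-readable token (``.token``) so pipeline
callers can branch on failure modes without string matching on prose.
"""


class OrthoflowError(Exception):
    """Base class for all package errors."""

    token = "error"

    def __init__(self, message: str | None = None):
        super().__init__(message or self.token)


class EmptyHistogramError(OrthoflowError):
    token = "empty-histogram"


class PeaksNotFoundError(OrthoflowError):
    token = "peaks-not-found"


class InvalidPeakError(OrthoflowError):
    token = "invalid-peak"


class InvalidMassError(OrthoflowError):
    token = "invalid-mass"


class InvalidRatioError(OrthoflowError):
    token = "invalid-ratios"


class InvalidFractionError(OrthoflowError):
    token = "invalid-fraction"


class InsufficientGroupsError(OrthoflowError):
    token = "insufficient-groups"


class DegenerateInputError(OrthoflowError):
    token = "degenerate-input"


class TreeParseError(OrthoflowError):
    token = "parse-error"


class MissingLengthsError(OrthoflowError):
    token = "missing-lengths"


class InsufficientTipsError(OrthoflowError):
    token = "insufficient-tips"


class DegenerateTreeError(OrthoflowError):
    token = "degenerate-tree"


class InconsistentInputError(OrthoflowError):
    token = "inconsistent-input"


class OffScaleError(OrthoflowError):
    token = "off-scale"
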
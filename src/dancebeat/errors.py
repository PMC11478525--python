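"""Exception hierarchy.

Everything derives from :class:`DanceBeatError` so callers can catch the
package's failures with one handler; the subclasses mirror the distinct
failure contracts of the pipeline stages (bad inputs, degenerate signals,
not enough data, undefined geometry).
"""


class DanceBeatError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(DanceBeatError, ValueError):
    """An argument violates a documented precondition."""


class InvalidSpecError(InvalidInputError):
    """A synthetic-fixture specification is out of range."""


class DegenerateEnvelopeError(DanceBeatError):
    """The onset envelope has zero variance and cannot be normalized."""


class InsufficientDataError(DanceBeatError):
    """Too little signal/data to perform the requested computation."""


class UndefinedAngleError(DanceBeatError, ValueError):
    """Joint angle undefined because keypoints coincide."""


class UndefinedSimilarityError(DanceBeatError):
    """Cosine similarity undefined (zero-norm vector)."""


class MissingFrameError(DanceBeatError, KeyError):
    """A keyframe index has no corresponding pose frame."""

    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(f"no pose data for keyframe indices {self.indices}")


class KeypointParseError(DanceBeatError):
    """A keypoint file could not be parsed."""


class ConfigError(DanceBeatError):
    """Configuration file or skeleton layout problem."""
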
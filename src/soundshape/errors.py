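"""Exception types shared across the package."""


class SoundShapeError(Exception):
    """Base class for all package errors."""


class AudioFormatError(SoundShapeError, IOError):
    """A file could not be read or written as audio."""


class ArgumentError(SoundShapeError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(SoundShapeError, ValueError):
    """Input is formally valid but carries no usable signal (e.g. all zeros)."""


class RankDeficiencyError(SoundShapeError, ValueError):
    """A regression design matrix is rank deficient (constant predictor)."""


class SeparationError(SoundShapeError, ValueError):
    """Logistic regression data are perfectly separated on a predictor."""
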
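"""Exception hierarchy for voicetp.

Every error raised by the package derives from :class:`VoiceTPError`, so
callers can catch one base class at pipeline boundaries.
"""


class VoiceTPError(Exception):
    """Base class for all voicetp errors."""


class ScoreParseError(VoiceTPError):
    """A MusicXML file could not be parsed; the message names the file/element."""


class EmptyPieceError(VoiceTPError):
    """A score produced no pitch events."""


class ManifestError(VoiceTPError):
    """A corpus manifest is missing, malformed, or references absent files."""


class PitchRangeError(VoiceTPError):
    """Pitches fall outside the writable/playable range."""


class DegenerateWindowError(VoiceTPError):
    """A pitch window is too short to encode (fewer than two tones)."""


class OrderMismatchError(VoiceTPError):
    """Context/target pairs of mixed order were passed to one estimator."""


class UndefinedInformationError(VoiceTPError):
    """Information content requested for a probability outside (0, 1]."""


class UndefinedEntropyError(VoiceTPError):
    """Conditional entropy requested for an empty distribution."""


class UndefinedCorrelationError(VoiceTPError):
    """Correlation requested for inputs with zero variance or too few points."""


class FeatureMatrixError(VoiceTPError):
    """A feature matrix could not be assembled (empty union, all-zero column...)."""


class GeneratorSpecError(VoiceTPError):
    """A synthetic-corpus generator specification is invalid."""
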
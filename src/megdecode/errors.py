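"""Exception types shared across the package."""


class MegdecodeError(Exception):
    """Base class for all package-specific errors."""


class InvalidWaveformError(MegdecodeError, ValueError):
    """Empty, silent, or non-finite audio input."""


class UnsupportedRateError(MegdecodeError, ValueError):
    """Audio sampling rate below the 16-kHz working rate."""


class EmptySpectrogramError(MegdecodeError, ValueError):
    """Stimulus shorter than one 10-ms analysis frame."""


class InsufficientDurationError(MegdecodeError, ValueError):
    """Spectrogram too short for modulation-rate filtering."""


class UndefinedSFMError(MegdecodeError, ValueError):
    """Spectral flatness requested for an all-zero frame."""


class UndefinedDistanceError(MegdecodeError, ValueError):
    """Correlation distance requested for a zero-variance vector."""


class SegmentationError(MegdecodeError, ValueError):
    """Malformed or overlapping phoneme segmentation."""


class TextGridParseError(SegmentationError):
    """Unreadable Praat TextGrid file."""


class EmptyAverageError(MegdecodeError, ValueError):
    """All trials rejected by the artifact threshold."""


class BaselineError(MegdecodeError, ValueError):
    """Epoch does not cover the prestimulus baseline window."""


class ResamplingError(MegdecodeError, ValueError):
    """Source sampling step does not divide the target step."""


class OutOfEpochError(MegdecodeError, ValueError):
    """A requested (frame, lag) combination falls outside the epoch."""


class DesignError(MegdecodeError, ValueError):
    """Infeasible synthetic stimulus design."""


class ConfigError(MegdecodeError, ValueError):
    """Invalid experiment configuration."""


class DegenerateTestError(MegdecodeError, ValueError):
    """Statistical test undefined for the given data (e.g. all-zero differences)."""


class EmptySchemeError(MegdecodeError, ValueError):
    """Pairing scheme admits no valid item pair."""


class UndefinedCorrelationError(MegdecodeError, ValueError):
    """Pearson correlation undefined (zero variance) in pair classification."""
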
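"""Exception types shared across the pipeline."""


class MousesongError(Exception):
    """Base class for all pipeline errors."""


class FormatError(MousesongError):
    """A file does not conform to the expected dialect (missing columns etc.)."""


class ValidationError(MousesongError):
    """In-memory data violate an invariant (non-monotone time, bad labels...)."""


class DegenerateSyllableError(MousesongError):
    """A syllable is too short to featurize (fewer than 2 frames)."""


class UncoveredTimeError(MousesongError):
    """An occupancy track does not cover the queried time point."""
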
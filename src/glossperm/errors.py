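"""Exception hierarchy shared across glossperm modules."""


class GlossPermError(Exception):
    """Base class for all glossperm errors."""


class ValidationError(GlossPermError, ValueError):
    """Invalid inputs or parameters (bad factor sets, non-finite values, ...)."""


class InsufficientRepeatsError(ValidationError):
    """A tuning curve enters analysis with fewer repeats than the accepted minimum."""


class MissingShuffledDataError(GlossPermError):
    """Shuffled-image control data are required for classification but absent."""


class FitError(GlossPermError):
    """Psychometric fitting failed in a way that cannot be flagged in-band."""
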
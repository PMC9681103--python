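"""Exception types shared across the pipeline stages."""


class EgowordsError(Exception):
    """Base class for all package-specific errors."""


class MalformedInputError(EgowordsError):
    """An input record could not be parsed (names the offending record)."""


class ConfigError(EgowordsError):
    """A configuration value or required file is missing or invalid."""


class ValidationError(EgowordsError):
    """An input row violates a documented invariant (names the row)."""


class TimelineRejectedError(EgowordsError):
    """A timeline spans less than the observation window and is excluded."""


class UndefinedRegressionError(EgowordsError):
    """Layer-size regression is undefined (zero variance in the regressor)."""


class UndefinedProfileError(EgowordsError):
    """A ring has no topic mass, so its semantic profile is undefined."""


class DegenerateSplitError(EgowordsError):
    """All shares are equal: no natural break exists for a 2-class split."""
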
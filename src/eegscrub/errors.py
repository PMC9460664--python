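"""Exception hierarchy for eegscrub."""


class EegscrubError(Exception):
    """Base class for all eegscrub errors."""


class InvalidInputError(EegscrubError, ValueError):
    """Raised when input data violate a precondition (non-finite, too short, ...)."""


class InvalidConfigError(EegscrubError, ValueError):
    """Raised when a configuration object is inconsistent with the data."""


class DegenerateInputError(EegscrubError, ValueError):
    """Raised when input is rank-deficient and no regularization was requested."""


class UndefinedMetricError(EegscrubError, ZeroDivisionError):
    """Raised when a quality metric is undefined (e.g. zero reference energy)."""
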
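"""Exception hierarchy for hdrisk."""


class HdriskError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HdriskError, ValueError):
    """An invalid cohort / pipeline configuration."""


class InsufficientDataError(HdriskError, ValueError):
    """Too few observations to carry out the requested computation."""


class SchemaError(HdriskError, ValueError):
    """A session table violates the documented CSV schema."""


class TrainingError(HdriskError, ValueError):
    """The classifier cannot be trained on the supplied data."""


class EvaluationError(HdriskError, ValueError):
    """Performance metrics are undefined for the supplied scores/labels."""
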
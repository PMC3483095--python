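"""Exception types raised across the pipeline."""


class OsteoburdenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OsteoburdenError, ValueError):
    """A configuration value is missing, malformed, or inconsistent."""


class VocabularyError(OsteoburdenError, ValueError):
    """A categorical value falls outside its configured vocabulary."""


class StratificationError(OsteoburdenError, ValueError):
    """A stratum has observed events but zero population at risk."""


class RecordError(OsteoburdenError, ValueError):
    """An individual record violates a field invariant (carries record ids)."""


class ConsistencyError(OsteoburdenError, ValueError):
    """A rendered total disagrees with the sum of its components."""
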
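"""Exception types shared across the package."""


class SubchromError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SubchromError, ValueError):
    """A configuration value is invalid; the message names the offending field."""


class ConsistencyError(SubchromError, ValueError):
    """Two inputs that must describe the same universe (map vs. config,
    summaries sharing one marker map, ...) disagree."""


class InputError(SubchromError, ValueError):
    """A data input violates its contract (bad alphabet, non-positive length)."""


class SampleLookupError(SubchromError, KeyError):
    """A requested sample or chromosome is absent from the data."""


class UndefinedResultError(SubchromError, ValueError):
    """The requested statistic is undefined for this input (e.g. no defined windows)."""
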
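"""Exception types shared across the pipeline."""


class TmsrespError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TmsrespError):
    """A configuration object is internally inconsistent (bad band name, counts < 1, ...)."""


class ParameterError(TmsrespError):
    """An operation was called with parameters outside its contract."""


class EmptyResultError(TmsrespError):
    """An operation produced an empty result where at least one element is required."""
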
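"""Exception hierarchy shared across the toolkit."""


class AtlasqError(Exception):
    """Base class for all toolkit errors."""


class FormatError(AtlasqError):
    """A file or directory does not match the expected on-disk layout."""


class ValidationError(AtlasqError):
    """Input data violates an invariant (non-integer counts, duplicate ids, ...)."""


class ParameterError(AtlasqError):
    """A parameter is out of its documented range."""


class ConfigurationError(AtlasqError):
    """Required metadata (columns, layers, fitted components) is missing."""


class EmptyResultError(AtlasqError):
    """An operation removed every cell/gene or produced an empty result."""
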
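"""Exception hierarchy shared across the pipeline."""


class OligomapError(Exception):
    """Base class for all package errors."""


class FormatError(OligomapError):
    """A file on disk does not conform to its declared format."""


class ValidationError(OligomapError):
    """An in-memory object violates a container invariant."""


class ConfigError(OligomapError):
    """A run configuration is malformed or inconsistent."""


class EmptyResultError(OligomapError):
    """A filtering step removed everything."""
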
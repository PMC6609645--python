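"""Exception hierarchy shared across the package."""


class MetmapError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MetmapError):
    """A spec/config object failed validation (bad counts, unknown keys, ...)."""


class ParseError(MetmapError):
    """An input file could not be parsed; the message names the offending line."""


class PreprocessError(MetmapError):
    """The transformation chain hit an unusable state (empty table, bad values)."""


class StageError(MetmapError):
    """A pipeline stage failed; downstream stages are skipped."""
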
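"""Exception hierarchy."""


class LaylinkError(Exception):
    """Base class for all package errors."""


class FormatError(LaylinkError):
    """A file does not conform to its declared dialect."""


class IntegrityError(LaylinkError):
    """Cross-record or record/text consistency violation."""


class ConfigError(LaylinkError):
    """Invalid runtime configuration."""


class TrainingError(LaylinkError):
    """Model fitting cannot proceed (e.g. single-class input)."""
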
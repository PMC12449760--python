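"""Exception hierarchy shared across the package."""


class PaleonetError(Exception):
    """Base class for all package-specific errors."""


class InputError(PaleonetError):
    """Invalid user-supplied data (bad counts file, out-of-range value...)."""


class UsageError(PaleonetError):
    """API misuse: wrong transform tag, precondition violation, etc."""


class ConfigError(PaleonetError):
    """Invalid configuration for a generator or a pipeline run."""
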
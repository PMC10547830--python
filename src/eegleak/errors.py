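"""Exception hierarchy shared across the package."""


class EEGLeakError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EEGLeakError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class FormatError(EEGLeakError, IOError):
    """A container file is corrupt, truncated, or has an unknown schema."""


class ContaminationError(EEGLeakError, RuntimeError):
    """A subject-grouped CV plan places one subject on both sides of a fold."""
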
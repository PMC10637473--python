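"""Exception types shared across the package."""


class PvstratError(Exception):
    """Base class for package-specific errors."""


class FormatError(PvstratError):
    """An input file does not conform to the expected layout."""


class EmptyDatasetError(PvstratError):
    """An input file contains no case reports."""


class UndefinedStratumError(PvstratError):
    """A stratum contains no reports, so disproportionality is undefined."""


class ConfigError(PvstratError):
    """A simulation or run configuration is invalid; the message names the field."""
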
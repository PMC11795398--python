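"""Exception hierarchy shared across the pipeline."""


class FlowPhenoError(Exception):
    """Base class for all package errors."""


class FCSParseError(FlowPhenoError):
    """Malformed FCS header, TEXT segment, or DATA segment."""


class UnsupportedFormatError(FCSParseError):
    """FCS file uses a datatype or mode outside the supported subset."""


class ConfigError(FlowPhenoError):
    """Invalid configuration value or missing required key."""


class InsufficientDataError(FlowPhenoError):
    """An operation received fewer events than its contract requires."""
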
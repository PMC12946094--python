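"""Exception types shared across the pipeline."""


class GlycogradError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GlycogradError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class ParseError(GlycogradError, ValueError):
    """A raw input file could not be parsed; the message carries a line number."""


class AnalysisError(GlycogradError, ValueError):
    """A computation was requested on input that cannot support it."""
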
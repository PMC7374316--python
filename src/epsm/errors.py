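"""Exception hierarchy for the epsm package."""


class EpsmError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(EpsmError):
    """An input file does not declare a required column."""


class ParseError(EpsmError):
    """A cell of an input file could not be parsed (carries the row index)."""


class ConfigurationError(EpsmError):
    """An invalid parameter value (sampling rate, cutoff, batch length, ...)."""


class PreprocessingError(EpsmError):
    """A trial cannot be preprocessed (e.g. too short for the filter)."""


class ProtocolError(EpsmError):
    """A cross-validation protocol precondition is violated."""
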
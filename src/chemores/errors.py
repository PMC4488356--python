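"""Exception hierarchy shared across the pipeline."""


class ChemoresError(Exception):
    """Base class for all package errors."""


class DataFormatError(ChemoresError, ValueError):
    """A file could not be parsed; the message names the offending location."""


class InputError(ChemoresError, ValueError):
    """Inputs violate an operation's preconditions."""


class ConfigError(ChemoresError, ValueError):
    """A configuration object is internally inconsistent."""
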
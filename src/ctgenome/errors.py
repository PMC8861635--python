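"""Exception hierarchy for the circuit-topology toolbox."""


class CTError(Exception):
    """Base class for all toolbox errors."""


class ParseError(CTError):
    """A file could not be parsed; the message names the offending line."""


class InputError(CTError):
    """Structurally invalid input (wrong shape, overlap, too few rows...)."""


class ParameterError(CTError):
    """An out-of-range or inconsistent analysis parameter."""


class DuplicateContactError(CTError):
    """Two identical contacts were compared; relations are defined on distinct pairs."""
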
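"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`SheetcheckError`, so callers (and the CLI) can distinguish
user-facing problems from genuine bugs.
"""


class SheetcheckError(Exception):
    """Base class for all errors raised by sheetcheck."""


class EncodingError(SheetcheckError):
    """Input bytes could not be decoded as UTF-8; names the byte offset."""


class AddressParseError(SheetcheckError):
    """A1-notation label could not be parsed."""


class AddressBoundsError(SheetcheckError):
    """A cell address lies outside the grid a report was built from."""


class ConfigurationError(SheetcheckError):
    """Rule override referenced an unknown rule id or used a bad value."""


class RulesetSpecError(SheetcheckError):
    """A custom rule-set document is malformed; carries the declaration path."""


class CapacityError(SheetcheckError):
    """More unique barcodes requested than the barcode length permits."""


class ParameterError(SheetcheckError):
    """A simulation parameter is out of its valid range."""
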
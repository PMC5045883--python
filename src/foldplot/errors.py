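"""Exception hierarchy shared by all modules."""


class FoldplotError(Exception):
    """Base class for all errors raised by this package."""


class InputError(FoldplotError):
    """A cell or value in the input data is malformed or unusable."""


class LayoutError(FoldplotError):
    """The structure of a table (columns, headers, ordering) is invalid."""


class ValidationError(FoldplotError):
    """A requested analysis is inappropriate for the data at hand."""
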
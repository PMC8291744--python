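"""Exception hierarchy shared across the package."""


class PlaceCellError(Exception):
    """Base class for all package errors."""


class ParameterError(PlaceCellError, ValueError):
    """A parameter value is outside its documented range."""


class InputError(PlaceCellError, ValueError):
    """An input table or array is malformed or inconsistent."""


class EmptyLibraryError(PlaceCellError):
    """A locomotion table contained no complete traversal."""


class EmptySessionError(PlaceCellError):
    """All frames of a session were excluded (e.g. by the running mask)."""
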
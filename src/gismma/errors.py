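"""Exception hierarchy shared across the package."""


class GismmaError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GismmaError, ValueError):
    """An input violates a documented contract (range, shape, finiteness)."""


class AlignmentError(GismmaError, ValueError):
    """Entity identifiers of two objects do not line up."""


class EntityLookupError(GismmaError, KeyError):
    """An entity identifier is not present in a network or matrix."""
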
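"""Exception types shared across the package."""


class DermspecError(ValueError):
    """Base class for all rejection signals raised by dermspec."""


class GridMismatchError(DermspecError):
    """Operands defined on different spectral grids."""


class InvalidBoxError(DermspecError):
    """A bounding box violates the coordinate invariants."""
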
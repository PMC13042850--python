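"""Exception types shared across the package."""


class EndospecError(Exception):
    """Base class for all package-specific errors."""


class GridMismatchError(EndospecError):
    """Spectra or cubes defined on different wavelength grids were combined."""


class DegenerateInputError(EndospecError):
    """Input carries no usable signal (constant or all-zero spectrum, etc.)."""


class ValidationError(EndospecError):
    """A parameter or container violates its documented invariants."""
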
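"""Exception types raised across the package."""


class InvalidInputError(ValueError):
    """An argument violates a documented precondition."""


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class LowPhotonsError(InvalidInputError):
    """A histogram carries too few photons for a reliable fit."""


class DegenerateFitError(RuntimeError):
    """Two fitted lifetimes collapsed onto each other; use fewer components."""
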
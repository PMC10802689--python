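"""Exception types shared across the pipeline."""


class PoremapError(Exception):
    """Base class for all pipeline errors."""


class InsufficientDataError(PoremapError):
    """Fewer localizations than the operation requires."""


class NoSignalError(PoremapError):
    """An image or profile carries no fittable signal."""


class NoPeakError(PoremapError):
    """A radial (or other) profile has no resolvable peak."""


class FitError(PoremapError):
    """A model fit failed to converge; the message names the dimension/stage."""
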
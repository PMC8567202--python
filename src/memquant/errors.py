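"""Exception hierarchy shared across the package."""


class MemquantError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MemquantError, ValueError):
    """Input violates a documented precondition or type invariant."""


class InsufficientDataError(MemquantError, ValueError):
    """Not enough observations to attempt the requested estimate."""


class FitError(MemquantError, RuntimeError):
    """A nonlinear fit failed to converge or the data carry no signal."""


class ProfileShapeError(MemquantError, ValueError):
    """A line profile does not show the expected two-membrane-peak shape.

    Raised so the caller can redraw the line (e.g. over a non-nuclear
    region) rather than silently returning a meaningless ratio.
    """
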
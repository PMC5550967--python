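"""Exception hierarchy: data errors vs numerical failures.

The CLI maps :class:`DataError` to exit code 1 and
:class:`NumericalError` to exit code 2.
"""


class MCProfileError(Exception):
    """Base class for all package errors."""


class DataError(MCProfileError):
    """Malformed or insufficient input data."""


class InsufficientPointsError(DataError):
    """Fewer profile points than the smoother or metamodel requires."""


class ProfileFormatError(DataError):
    """A profile table failed to parse or validate."""


class NumericalError(MCProfileError):
    """A numerical procedure failed on structurally valid input."""


class DegenerateDesignError(NumericalError):
    """All design points identical; no local regression possible."""


class DegenerateFitError(NumericalError):
    """Weighted design matrix rank-deficient at an evaluation point."""


class NonConcaveFitError(NumericalError):
    """The quadratic metamodel has non-negative curvature.

    The profile shows no local maximum at the scale probed; widen the
    profile range or add evaluation points.
    """
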
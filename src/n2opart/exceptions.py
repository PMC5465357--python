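"""Exception hierarchy for n2opart.

Every validated failure raises a subclass of :class:`N2OPartError`, so callers
(including the CLI) can distinguish bad inputs from genuine bugs.
"""


class N2OPartError(Exception):
    """Base class for all package-specific errors."""


class InvalidValueError(N2OPartError, ValueError):
    """A numeric argument is non-finite or otherwise invalid."""


class ConfigurationError(N2OPartError, ValueError):
    """A configuration parameter is outside its physically meaningful range."""


class DegenerateInputError(N2OPartError, ValueError):
    """Inputs are formally valid but the operation is undefined on them
    (e.g. zero total concentration in a mixing calculation)."""


class UninformativeTracerError(N2OPartError, ValueError):
    """The precursor's oxygen-isotope anomaly is too close to zero for the
    transfer ratio to carry information."""


class MissingMeasurementError(N2OPartError, ValueError):
    """A required measured quantity is absent from a record; the message
    names the missing field."""


class CollinearityError(N2OPartError, ValueError):
    """The endmember geometry is rank-deficient, so the mass-balance system
    cannot be solved; the message names the offending processes when the
    degeneracy is a pairwise duplicate."""


class InfeasibleSolutionError(N2OPartError, ValueError):
    """All raw fractional contributions are non-positive, so clipping and
    renormalisation are undefined."""


class NoSteadyStateError(N2OPartError, ValueError):
    """No trailing window of the incubation series satisfies the
    steady-state trend criterion."""


class InsufficientDataError(N2OPartError, ValueError):
    """Too few data points to perform the requested computation."""


class TableParseError(N2OPartError, ValueError):
    """A delimited input table violates the documented schema; the message
    locates the problem (file, line, column)."""
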
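"""Exception hierarchy for thermoprop.

All validation failures raise subclasses of :class:`ThermopropError`, which
itself subclasses :class:`ValueError` so callers can catch either.
"""


class ThermopropError(ValueError):
    """Base class for all thermoprop validation and modelling errors."""


class InvalidInputError(ThermopropError):
    """Input data violates a precondition (too few points, bad values...)."""


class DegenerateDesignError(InvalidInputError):
    """Regression design is degenerate (e.g. all x values identical)."""


class NoInactivationError(ThermopropError):
    """Survivor-curve slope is non-negative: D_T is undefined."""


class TemperatureDependenceError(ThermopropError):
    """log10(D_T) does not decrease with temperature: z is undefined."""


class ParseError(ThermopropError):
    """A CSV input could not be parsed; message carries the line number."""
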
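"""Exception hierarchy shared across stepcoach modules."""


class StepcoachError(Exception):
    """Base class for all stepcoach errors."""


class ValidationError(StepcoachError):
    """An input value violates a documented invariant."""


class ParseError(StepcoachError):
    """A data file could not be parsed; the message names the offending line."""


class CatalogError(StepcoachError):
    """A message/action/barrier catalog is malformed or cannot serve a request."""


class UndefinedValueError(StepcoachError):
    """A quantity is undefined for the given input (e.g. empty denominator)."""
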
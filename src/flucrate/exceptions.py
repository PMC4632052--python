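"""Exception hierarchy for flucrate."""


class FlucrateError(Exception):
    """Base class for all flucrate errors."""


class InvalidParameterError(FlucrateError, ValueError):
    """A model or algorithm parameter is outside its domain."""


class ParseError(FlucrateError, ValueError):
    """Input text could not be parsed into a fluctuation dataset."""


class ValidationError(FlucrateError, ValueError):
    """A dataset violates a structural constraint (e.g. negative counts)."""


class EmptyDatasetError(ValidationError):
    """An operation that needs data received an empty dataset."""


class EstimationError(FlucrateError, RuntimeError):
    """Parameter estimation failed (e.g. fitness unidentifiable)."""


class UnidentifiableError(EstimationError):
    """The data carry no information about the requested parameter."""


class GofUnavailableError(FlucrateError, RuntimeError):
    """Too few cultures (or a degenerate model) to form a chi-square test."""
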
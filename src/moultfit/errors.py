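"""Exception hierarchy shared across the package."""


class MoultFitError(Exception):
    """Base class for all package errors."""


class DataError(MoultFitError):
    """Input data violate a precondition (too few points, non-positive values,
    duplicated rows, missing required measurements)."""


class ParameterError(MoultFitError):
    """A parameter is outside its admissible range."""
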
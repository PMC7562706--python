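"""Exception hierarchy shared across the pipeline."""


class CarrierAifError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(CarrierAifError, ValueError):
    """A scalar or structured input violates a documented precondition."""


class UnitError(CarrierAifError, ValueError):
    """Incompatible or unrecognized measurement units."""


class FitError(CarrierAifError, ValueError):
    """A regression or estimator cannot be computed from the given data."""


class SchemaError(CarrierAifError, ValueError):
    """A tabular input does not conform to its documented column contract."""
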
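"""Exception types raised across the package."""


class InvalidArgument(ValueError):
    """An argument violates a documented precondition."""


class DegeneratePredictor(ValueError):
    """A predictor has too few distinct values to support its transform."""


class DegenerateFit(ValueError):
    """The outcome is constant (or single-class) so no model can be fit."""


class UnimputableColumn(ValueError):
    """A column is entirely missing and cannot be imputed."""


class SchemaError(ValueError):
    """Input data do not match the declared cohort schema."""


class UndefinedAUC(ValueError):
    """AUC requested but only one outcome class is present."""


class UndefinedChange(ValueError):
    """Baseline-adjusted change requested with a chance-level reference AUC."""


class EmptyMetaFeatures(ValueError):
    """Every patient was in-sample in every bootstrap replicate."""


class ProtocolError(RuntimeError):
    """An evaluation protocol was invoked without its required inputs."""
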
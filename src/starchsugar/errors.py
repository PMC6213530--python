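"""Exception hierarchy shared across the pipeline stages."""


class StarchSugarError(Exception):
    """Base class for all package errors."""


class MissingDataError(StarchSugarError):
    """A required field is MISSING (e.g. a proximate needed for arithmetic)."""


class IncompleteProfileError(StarchSugarError):
    """A saccharide profile has at least one MISSING component."""


class InvariantError(StarchSugarError):
    """A domain invariant was violated (e.g. water > 100, free > total sugar)."""


class DivisionError(StarchSugarError):
    """A scaling denominator (dry weight) is zero."""


class DependencyError(StarchSugarError):
    """A recipe ingredient has no assigned value yet."""


class CycleError(StarchSugarError):
    """Recipes reference each other cyclically."""


class EmptySetError(StarchSugarError):
    """An aggregation was requested over an empty collection."""


class UnknownFoodError(StarchSugarError):
    """A dietary record references a food code absent from the database."""


class EstimationError(StarchSugarError):
    """Habitual-intake estimation is impossible (e.g. all persons single-day)."""


class DomainError(StarchSugarError):
    """A value is outside the mathematical domain of a transform."""


class SchemaError(StarchSugarError):
    """An input file does not match the expected column schema."""


class ParseError(StarchSugarError):
    """A cell could not be parsed; message carries row/column context."""


class ConfigError(StarchSugarError):
    """A configuration is internally inconsistent or infeasible."""
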
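"""Named validation and computation errors raised across the package."""


class SicompError(Exception):
    """Base class for all package errors."""


class ValidationError(SicompError, ValueError):
    """Base class for input-validation failures."""


class NonSquareMatrixError(ValidationError):
    """A diallel matrix file is not square."""


class ScoreRangeError(ValidationError):
    """A compatibility score is outside the 0–10 ordinal scale or non-integer."""


class DuplicateGenotypeError(ValidationError):
    """A genotype id appears more than once."""


class UnknownFamilyError(ValidationError):
    """A family label is not present in the matrix metadata."""


class UndefinedCorrelationError(SicompError):
    """Too few shared cells (or zero variance) to define a correlation."""


class NoSharedCoordinatesError(SicompError):
    """A profile pair shares no jointly observed coordinate."""


class NoInflectionError(SicompError):
    """A quantile series is degenerate (constant scores): no inflection exists."""


class UndefinedRSquaredError(SicompError):
    """All real scores are identical: the R² denominator is zero."""


class UnsatisfiableConfigError(SicompError):
    """Simulation cannot proceed (e.g. a mother incompatible with the whole
    pollen cloud under zero self-fertility leak)."""


class ConfigError(ValidationError):
    """A run-configuration field is missing or out of range."""
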
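"""Exception hierarchy for the pipeline.

Configuration problems (bad column maps, thresholds out of range) and data
problems (invariant violations in input rows) are kept distinct so callers —
in particular the CLI — can map them to different exit codes.
"""


class KynscanError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(KynscanError):
    """A configuration problem: missing column, threshold out of range."""


class DataError(KynscanError):
    """A data problem: invariant violation in input rows."""


class ValidationError(DataError):
    """Row-level validation failure; carries the offending rows."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class AlleleMismatchError(DataError):
    """Requested allele is not one of the record's two alleles."""


class MonomorphicVariantError(DataError):
    """A variant with zero dosage variance where correlation is required."""


class MissingVariantError(DataError):
    """A required variant is absent from a genotype matrix or LD reference."""


class MissingDemographicsError(DataError):
    """A person appears in event counts but not in the demographics table."""


class DesignError(DataError):
    """Rank-deficient or otherwise unusable regression design."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class DegenerateInstrumentsError(DataError):
    """All exposure effects are zero: no usable instruments."""


class InsufficientInstrumentsError(DataError):
    """Fewer instruments than the estimator requires."""


class UndefinedRatioError(DataError):
    """Wald ratio with a zero exposure effect."""
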
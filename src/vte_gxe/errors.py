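"""Exception hierarchy for cohort ingestion and analysis."""


class VteGxeError(Exception):
    """Base class for all package errors."""


class SchemaError(VteGxeError):
    """A required column or config key is missing or malformed."""


class GenotypeParseError(VteGxeError):
    """A genotype string could not be interpreted for a SNP."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"{message} (row {row})")
        self.row = row


class ValidationError(VteGxeError):
    """A value violates a data-model invariant (range, uniqueness, dosage)."""


class ConfigurationError(VteGxeError):
    """An analysis was configured inconsistently (e.g. weighted score without weights)."""


class DegenerateDataError(VteGxeError):
    """The requested estimate is undefined on these data (empty stratum, constant column)."""
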
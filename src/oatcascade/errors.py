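"""Exception types shared across the pipeline."""


class OatCascadeError(Exception):
    """Base class for all package errors."""


class CohortConfigError(OatCascadeError):
    """Invalid synthetic-cohort configuration; the message names the field."""


class SchemaError(OatCascadeError):
    """An input table is missing a required column or has the wrong dtype."""


class RowValidationError(OatCascadeError):
    """One or more rows failed validation; the message carries row numbers."""


class ConvergenceError(OatCascadeError):
    """A model fit failed to converge (e.g. separation); names the covariate."""
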
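"""Exception hierarchy shared across the package."""


class VatPredictError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(VatPredictError):
    """A required column is missing or the input table is malformed."""


class CohortValidationError(VatPredictError):
    """One or more rows violate the subject-record invariants.

    Carries ``diagnostics``: a list of ``(row_index, field, message)`` tuples.
    """

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        lines = "; ".join(f"row {r}: {f}: {m}" for r, f, m in self.diagnostics[:20])
        extra = "" if len(self.diagnostics) <= 20 else f" (+{len(self.diagnostics) - 20} more)"
        super().__init__(f"cohort validation failed: {lines}{extra}")


class MissingDataError(VatPredictError):
    """An operation needs a field the record does not carry."""

    def __init__(self, fields, context=""):
        if isinstance(fields, str):
            fields = [fields]
        self.fields = list(fields)
        msg = f"missing required field(s): {', '.join(self.fields)}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class DomainError(VatPredictError):
    """Inputs are outside the mathematical domain of a formula."""


class DegenerateInputError(VatPredictError):
    """Inputs are structurally unusable (e.g. single-class labels for ROC)."""


class FitError(VatPredictError):
    """Model fitting cannot proceed (too few observations, rank collapse...)."""
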
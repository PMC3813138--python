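"""Exception hierarchy.

Every failure mode raised by the package derives from :class:`GfaQsarError`
so callers (and the CLI) can catch one type.  Data problems and numerical
degeneracies get distinct classes because they call for different fixes:
a ``SchemaError`` means the input file is wrong, a ``SingularDesignError``
means the requested model cannot be estimated from an otherwise valid table.
"""


class GfaQsarError(Exception):
    """Base class for all package errors."""


class SchemaError(GfaQsarError):
    """A required descriptor column is missing or misnamed."""


class TableParseError(GfaQsarError):
    """A cell could not be parsed as a number; carries row and column."""


class ValidationError(GfaQsarError):
    """A loaded table violates a structural invariant (duplicate ids,
    inconsistent printed residuals, ...)."""


class InsufficientDataError(GfaQsarError):
    """Too few training records for the number of requested terms."""


class SingularDesignError(GfaQsarError):
    """Design matrix is rank deficient beyond the condition threshold."""

    def __init__(self, message, collinear_terms=()):
        super().__init__(message)
        self.collinear_terms = tuple(collinear_terms)


class FoldSingularError(GfaQsarError):
    """A leave-one-out fold produced a singular design; names the record."""

    def __init__(self, message, ligand_id=None):
        super().__init__(message)
        self.ligand_id = ligand_id


class DegeneratePenaltyError(GfaQsarError):
    """Friedman lack-of-fit penalty (c + d*p)/n reaches or exceeds 1."""


class DegenerateDescriptorError(GfaQsarError):
    """A descriptor column has zero variance where variance is required."""


class EvaluationError(GfaQsarError):
    """A record lacks a descriptor the model needs; names it."""


class ComponentCountError(GfaQsarError):
    """Requested PLS components exceed the rank of the centered design."""


class ConfigError(GfaQsarError):
    """Infeasible or inconsistent search / run configuration."""


class SearchFailureError(GfaQsarError):
    """Every candidate model in a GFA run was singular."""


class SyntheticSpecError(GfaQsarError):
    """Synthetic-data specification is internally inconsistent."""
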
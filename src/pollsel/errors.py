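"""Exception hierarchy for the pollsel package."""


class PollselError(Exception):
    """Base class for all pollsel errors."""


class SchemaError(PollselError):
    """A required column is missing or a cell cannot be parsed."""


class ValidationError(PollselError):
    """A record violates a study-table invariant."""


class SingularDesignError(PollselError):
    """The design matrix is rank deficient."""


class InsufficientDataError(PollselError):
    """Too few rows for the requested fit."""


class DegenerateTraitError(PollselError):
    """A trait has zero variance within a standardization group."""


class GroupError(PollselError):
    """A population/morph/treatment stratum is missing or too small."""
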
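"""Shared exception types."""


class PedsTrissError(Exception):
    """Base class for package errors."""


class InvalidInputError(PedsTrissError, ValueError):
    """An input value is outside its legal range or malformed."""


class NoInjuryError(PedsTrissError, ValueError):
    """An AIS profile with no coded injury (all six regions zero)."""


class DegenerateDataError(PedsTrissError, ValueError):
    """Data cannot support the requested computation (e.g. single outcome class)."""


class SeparationError(PedsTrissError, RuntimeError):
    """Logistic fit failed to converge due to (quasi-)complete separation."""


class ValidationUnstableError(PedsTrissError, RuntimeError):
    """Too many bootstrap resamples failed to refit."""


class CohortParseError(PedsTrissError, ValueError):
    """A cohort file could not be parsed."""
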
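"""Exception hierarchy for rfacurve.

All package errors derive from :class:`RfaError` so callers can catch one
base class; the subclasses distinguish file-format problems, bad data,
invalid cohort metadata and degenerate statistical input.
"""


class RfaError(Exception):
    """Base class for all rfacurve errors."""


class FormatError(RfaError):
    """A file does not have the expected layout (missing/ambiguous columns)."""


class DataError(RfaError):
    """A file parsed, but its contents violate a data requirement."""


class ValidationError(RfaError):
    """Cohort metadata is inconsistent (unknown group, duplicate sample id)."""


class NoRolloffError(RfaError):
    """Threshold roll-off detection found no crossing of the target level.

    Carries the maximum impedance reached so callers can report how far the
    curve got; signals an aborted or failed ablation rather than a bug.
    """

    def __init__(self, message: str, max_impedance: float):
        super().__init__(message)
        self.max_impedance = float(max_impedance)


class DegenerateInputError(RfaError):
    """Statistical input on which the requested test is undefined."""


class SpecError(RfaError):
    """A synthetic curve or cohort specification violates its invariants."""
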
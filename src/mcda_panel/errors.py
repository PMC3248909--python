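"""Exception hierarchy for panel validation and computation failures.

Exit-code mapping used by the CLI: validation errors (subclasses of
:class:`PanelValidationError`) exit with 2, computation errors
(:class:`ComputationError`) with 3.
"""


class MCDAPanelError(Exception):
    """Base class for all package errors."""


class PanelValidationError(MCDAPanelError):
    """Input data or configuration failed validation."""


class IncompletePanelError(PanelValidationError):
    """A rating matrix is missing required rater x criterion cells."""


class EmptyPanelError(PanelValidationError):
    """A panel contains no raters."""


class ScaleViolationError(PanelValidationError):
    """A rating lies outside the declared scale bounds or is non-integer."""


class AlignmentError(PanelValidationError):
    """Two matrices that must share rater/criterion sets do not."""


class PanelParseError(PanelValidationError):
    """A delimited panel file is malformed; message names the location."""


class ConfigurationError(PanelValidationError):
    """Run configuration or criteria configuration is invalid."""


class ProfileError(PanelValidationError):
    """A synthetic committee profile is internally inconsistent."""


class ComputationError(MCDAPanelError):
    """A statistic is undefined for the given data."""


class UndefinedICCError(ComputationError):
    """ICC is undefined because the data carry no unit-to-unit variance."""


class InfeasibleTargetError(ComputationError):
    """No integer rating vector reproduces the requested mean/SD summary.

    Carries ``nearest`` — a list of (mean, sd) summaries achievable on the
    given scale that are closest to the requested target.
    """

    def __init__(self, message: str, nearest=None):
        super().__init__(message)
        self.nearest = nearest or []
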
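"""Exception and warning types raised by lipocharge."""


class LipochargeError(ValueError):
    """Base class for domain errors raised by this package."""


class DomainError(LipochargeError):
    """An input lies outside the physically admissible domain."""


class InsufficientDataError(LipochargeError):
    """Too few data points remain for the requested fit."""


class SignConventionError(LipochargeError):
    """A fitted branch slope violates the sign required by the model
    (acid-branch slope must be positive, base-branch slope negative)."""


class NonPhysicalRootError(LipochargeError):
    """The intercept system admits no positive (K_AH, K_BOH) pair."""


class ConvergenceFailureError(LipochargeError):
    """The nonlinear least-squares refinement did not converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoIsoelectricPointError(LipochargeError):
    """The model charge density does not change sign on pH in [0, 14]."""


class FormatError(LipochargeError):
    """An input file does not match any accepted column schema."""


class DuplicatePHWarning(UserWarning):
    """Duplicate pH values were found and averaged."""


class TieWarning(UserWarning):
    """Two salts have exactly equal binding constants; ranking kept input order."""
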
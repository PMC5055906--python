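"""Exception hierarchy.

``ExcludedDrugError`` mirrors the screening rule of the prediction method:
a drug whose dissolution never completes in either test fluid cannot be
assigned a theoretical dissolution rate and is dropped from scoring rather
than given a made-up number.
"""


class AST120DDIError(Exception):
    """Base class for all package-specific errors."""


class InputDataError(AST120DDIError, ValueError):
    """Malformed or insufficient input data (bad CSV, too few points, ...)."""


class NoDissolutionError(InputDataError):
    """The measured profile never reaches 1 % dissolved; no lag time exists."""


class ExcludedDrugError(AST120DDIError):
    """Complete dissolution was not reached in either fluid; the drug
    cannot be scored by the interaction prediction method."""


class FitConvergenceError(AST120DDIError, RuntimeError):
    """Nonlinear least squares failed to converge after all restarts."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
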